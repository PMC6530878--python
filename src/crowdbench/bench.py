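"""Benchmark orchestration: models x stimuli -> crowding/uncrowding verdicts.

For every model and category the bench computes the vernier-alone
reference, scores the (alone, one flanker, many flankers) triplet, maps the
raw scores onto the threshold scale through the model's designated readout
chain, and classifies the resulting threshold triplet:

* crowding detected iff t1 > t0 * (1 + margin);
* given crowding, uncrowding iff tN < t1 * (1 - margin);
* otherwise crowding-only; without crowding, none.

The verdict grid is the machine analogue of the qualitative summary matrix:
green cells (uncrowding) should appear consistently only for the grouping
model.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import default_config
from .readouts import (RawScore, ThresholdLike, apply_psychometric,
                       fit_psychometric, to_threshold)
from .stimgen import StimulusSet, build_database

logger = logging.getLogger(__name__)

MODEL_NAMES = ("wc", "v1", "fourier", "grouping")


class Verdict(Enum):
    NONE = "none"
    CROWDING_ONLY = "crowding_only"
    UNCROWDING = "uncrowding"
    NOT_RUN = "not_run"


@dataclass
class ScoreTriplet:
    t0: float                     # vernier alone (threshold-like)
    t1: float                     # 1 flanker
    tN: float                     # many flankers
    category: str = ""
    model: str = ""
    raw: tuple[float, float, float] | None = None
    replicate_spread: float = 0.0

    def __post_init__(self):
        if not (self.t0 > 0 and self.t1 > 0 and self.tN > 0):
            raise ValueError("thresholds must be positive")


@dataclass
class VerdictMatrix:
    cells: dict[tuple[str, str], Verdict] = field(default_factory=dict)
    triplets: dict[tuple[str, str], ScoreTriplet] = field(default_factory=dict)
    errors: dict[tuple[str, str], str] = field(default_factory=dict)
    rel_margin: float = 0.10

    def verdict(self, category: str, model: str) -> Verdict:
        return self.cells.get((category, model), Verdict.NOT_RUN)

    @property
    def categories(self) -> list[str]:
        return sorted({k[0] for k in self.cells})

    @property
    def models(self) -> list[str]:
        return sorted({k[1] for k in self.cells})


def classify_triplet(triplet: ScoreTriplet | tuple,
                     rel_margin: float = 0.10) -> Verdict:
    """Classify a threshold triplet as uncrowding / crowding-only / none."""
    if isinstance(triplet, ScoreTriplet):
        t0, t1, tn = triplet.t0, triplet.t1, triplet.tN
    else:
        t0, t1, tn = (x.value if isinstance(x, ThresholdLike) else float(x)
                      for x in triplet)
    for v in (t0, t1, tn):
        if not np.isfinite(v) or v <= 0:
            raise ValueError("thresholds must be positive and finite")
    if t1 <= t0 * (1 + rel_margin):
        return Verdict.NONE
    if tn < t1 * (1 - rel_margin):
        return Verdict.UNCROWDING
    return Verdict.CROWDING_ONLY


def load_human_thresholds() -> dict[str, tuple[float, float, float]]:
    """Relative human threshold triplets (alone, one, many) per category."""
    ref = importlib.resources.files("crowdbench.data") / "human_thresholds.yaml"
    data = yaml.safe_load(ref.read_text())
    return {k: tuple(float(x) for x in v) for k, v in data.items()}


# ---------------------------------------------------------------------------
# per-model scoring chains
# ---------------------------------------------------------------------------

def _wc_thresholds(db: StimulusSet, categories, config: dict) -> dict:
    from .wilson_cowan import WCParams, wc_reference, wc_score
    params = WCParams.from_config(config)
    human = load_human_thresholds()
    train_cat = config["wc"]["train_category"]
    shift = config["readouts"]["xcorr_max_shift"]

    def raw_triplet(category):
        ids = db.triplet_ids(category)
        ref = wc_reference(db.condition(ids[0]), params)
        return tuple(wc_score(db.condition(cid), ref, params,
                              max_shift=shift).value for cid in ids)

    train_raw = raw_triplet(train_cat)
    fit = fit_psychometric(train_raw, human[train_cat], train_category=train_cat)
    out = {}
    for cat in categories:
        raw = train_raw if cat == train_cat else raw_triplet(cat)
        thr = tuple(apply_psychometric(fit, c).value for c in raw)
        out[cat] = ScoreTriplet(*thr, category=cat, model="wc", raw=raw)
    return out


def _v1_thresholds(db: StimulusSet, categories, config: dict) -> dict:
    from .v1_saliency import V1Params, v1_reference, v1_score
    params = V1Params.from_config(config)
    scale = config["readouts"]["threshold_scale"]
    ceiling = config["readouts"]["threshold_ceiling"]
    out = {}
    for cat in categories:
        ids = db.triplet_ids(cat)
        ref = v1_reference(db.condition(ids[0]), params)
        raw = tuple(v1_score(db.condition(cid), ref, params).value
                    for cid in ids)
        thr = tuple(to_threshold(c, scale, ceiling).value for c in raw)
        out[cat] = ScoreTriplet(*thr, category=cat, model="v1", raw=raw)
    return out


def _fourier_thresholds(db: StimulusSet, categories, config: dict) -> dict:
    from .fourier import PassBand, score_triplet_for_band
    band = PassBand(*config["fourier"]["default_band"])
    scale = config["readouts"]["threshold_scale"]
    ceiling = config["readouts"]["threshold_ceiling"]
    shift = config["fourier"]["xcorr_max_shift"]
    out = {}
    for cat in categories:
        raw = score_triplet_for_band(db, cat, band, max_shift=shift)
        thr = tuple(to_threshold(c, scale, ceiling).value for c in raw)
        out[cat] = ScoreTriplet(*thr, category=cat, model="fourier", raw=raw)
    return out


def _grouping_thresholds(db: StimulusSet, categories, config: dict,
                         seed: int = 0) -> dict:
    from .grouping import GroupingParams, grouping_score, prepare_stimulus
    params = GroupingParams.from_config(config)
    n_rep = config["bench"]["n_replicates"]
    scale = config["readouts"]["threshold_scale"]
    ceiling = config["readouts"]["threshold_ceiling"]
    out = {}
    for cat in categories:
        ids = db.triplet_ids(cat)
        raw, spreads = [], []
        for cid in ids:
            prepared = tuple(prepare_stimulus(img, params)
                             for img in db.condition(cid))
            reps = [grouping_score(db.condition(cid), params,
                                   seed=seed + 101 * r, prepared=prepared).value
                    for r in range(n_rep)]
            raw.append(float(np.mean(reps)))
            spreads.append(float(np.std(reps)))
        thr = tuple(to_threshold(c, scale, ceiling).value for c in raw)
        out[cat] = ScoreTriplet(*thr, category=cat, model="grouping",
                                raw=tuple(raw),
                                replicate_spread=float(np.max(spreads)))
    return out


_MODEL_RUNNERS = {
    "wc": _wc_thresholds,
    "v1": _v1_thresholds,
    "fourier": _fourier_thresholds,
    "grouping": _grouping_thresholds,
}


def run_benchmark(models=MODEL_NAMES, database: StimulusSet | None = None,
                  config: dict | None = None, categories=None,
                  seed: int = 0) -> VerdictMatrix:
    """Score every requested model on every category triplet and classify.

    A model failure on a category leaves the cell NOT_RUN with the error
    recorded (the summary matrix's gray cells).
    """
    cfg = config or default_config()
    db = database or build_database(cfg)
    cats = list(categories) if categories is not None else db.categories()
    margin = cfg["bench"]["rel_margin"]
    matrix = VerdictMatrix(rel_margin=margin)
    for model in models:
        if model not in _MODEL_RUNNERS:
            raise ValueError(f"unknown model {model!r}")
        runner = _MODEL_RUNNERS[model]
        kwargs = {"seed": seed} if model == "grouping" else {}
        try:
            triplets = runner(db, cats, cfg, **kwargs)
        except Exception as exc:  # whole-model failure
            logger.exception("model %s failed", model)
            for cat in cats:
                matrix.cells[(cat, model)] = Verdict.NOT_RUN
                matrix.errors[(cat, model)] = repr(exc)
            continue
        for cat in cats:
            try:
                trip = triplets[cat]
                matrix.triplets[(cat, model)] = trip
                matrix.cells[(cat, model)] = classify_triplet(trip, margin)
            except Exception as exc:
                logger.exception("model %s failed on %s", model, cat)
                matrix.cells[(cat, model)] = Verdict.NOT_RUN
                matrix.errors[(cat, model)] = repr(exc)
    return matrix


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def matrix_to_frame(matrix: VerdictMatrix) -> pd.DataFrame:
    rows = []
    for (cat, model), verdict in sorted(matrix.cells.items()):
        trip = matrix.triplets.get((cat, model))
        rows.append({
            "category": cat, "model": model, "verdict": verdict.value,
            "t0": trip.t0 if trip else np.nan,
            "t1": trip.t1 if trip else np.nan,
            "tN": trip.tN if trip else np.nan,
            "raw0": trip.raw[0] if trip and trip.raw else np.nan,
            "raw1": trip.raw[1] if trip and trip.raw else np.nan,
            "rawN": trip.raw[2] if trip and trip.raw else np.nan,
            "replicate_spread": trip.replicate_spread if trip else np.nan,
            "error": matrix.errors.get((cat, model), ""),
        })
    return pd.DataFrame(rows)


def matrix_to_dict(matrix: VerdictMatrix) -> dict:
    out: dict = {"rel_margin": matrix.rel_margin, "cells": {}}
    for (cat, model), verdict in sorted(matrix.cells.items()):
        cell: dict = {"verdict": verdict.value}
        trip = matrix.triplets.get((cat, model))
        if trip is not None:
            cell["thresholds"] = [trip.t0, trip.t1, trip.tN]
            if trip.raw is not None:
                cell["raw"] = list(trip.raw)
            cell["replicate_spread"] = trip.replicate_spread
        if (cat, model) in matrix.errors:
            cell["error"] = matrix.errors[(cat, model)]
        out["cells"].setdefault(cat, {})[model] = cell
    return out


def matrix_from_dict(data: dict) -> VerdictMatrix:
    matrix = VerdictMatrix(rel_margin=data.get("rel_margin", 0.10))
    for cat, per_model in data["cells"].items():
        for model, cell in per_model.items():
            matrix.cells[(cat, model)] = Verdict(cell["verdict"])
            if "thresholds" in cell:
                matrix.triplets[(cat, model)] = ScoreTriplet(
                    *cell["thresholds"], category=cat, model=model,
                    raw=tuple(cell["raw"]) if "raw" in cell else None,
                    replicate_spread=cell.get("replicate_spread", 0.0))
            if "error" in cell:
                matrix.errors[(cat, model)] = cell["error"]
    return matrix


_VERDICT_COLORS = {
    Verdict.UNCROWDING: (0.2, 0.7, 0.3),
    Verdict.CROWDING_ONLY: (0.85, 0.25, 0.2),
    Verdict.NONE: (0.95, 0.9, 0.6),
    Verdict.NOT_RUN: (0.6, 0.6, 0.6),
}


def export_matrix(matrix: VerdictMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the verdict matrix as long-form CSV, nested JSON and a
    color-grid PNG; idempotent."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "verdicts.csv"
    matrix_to_frame(matrix).to_csv(csv_path, index=False)
    json_path = out / "verdicts.json"
    with open(json_path, "w") as fh:
        json.dump(matrix_to_dict(matrix), fh, indent=1, sort_keys=True)

    cats, models = matrix.categories, matrix.models
    grid = np.zeros((len(cats), len(models), 3))
    for i, cat in enumerate(cats):
        for j, model in enumerate(models):
            grid[i, j] = _VERDICT_COLORS[matrix.verdict(cat, model)]
    fig, ax = plt.subplots(figsize=(2 + len(models), 1 + 0.4 * len(cats)))
    ax.imshow(grid, aspect="auto")
    ax.set_xticks(range(len(models)), models)
    ax.set_yticks(range(len(cats)), cats)
    ax.set_title("crowding / uncrowding verdicts")
    ax.legend(handles=[Patch(color=c, label=v.value)
                       for v, c in _VERDICT_COLORS.items()],
              bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    png_path = out / "verdicts.png"
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "json": json_path, "png": png_path}
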