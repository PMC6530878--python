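"""Default configuration for the stimulus generator, the models and the bench.

Everything numeric lives here so that a single YAML file can override any
constant.  The stimulus geometry defaults put one flanker inside Bouma's
window at the nominal eccentricity and extend the 7-flanker row well beyond
it; model constants realize the canonical behaviour of each model family and
are deliberately exposed rather than hard-coded.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "stimuli": {
        "canvas": [160, 560],          # rows, cols (px)
        "px_per_deg": 32,
        "eccentricity_deg": 4.0,       # metadata only
        "vernier": {
            "bar_length": 20,
            "bar_width": 2,
            "vertical_gap": 2,
            "offset": 2,
        },
        "flanker_size": 48,            # bounding-box side / line length (px)
        "flanker_spacing": 56,         # center-to-center (px)
        "gestalt_spacing": 64,         # cuboid drawings need wider slots
        "grid_row_spacing": 52,        # 3x7 grids
        "grid_element_size": 40,       # non-central grid elements
        "stroke_width": 1,
        "irregular_seed": 7,           # recorded in the manifest
        "irregular_jitter": 4.0,       # px, radial jitter of polygon vertices
    },
    "readouts": {
        "xcorr_max_shift": 2,
        "threshold_scale": 1.0,
        "threshold_ceiling": 1e6,
    },
    "wc": {
        "dog": {"sigma_center": 1.2, "sigma_surround": 2.4, "gain": 20.0},
        "rf_lengths": [20, 42, 48],    # vernier bar, whole vernier, flanker
        "rf_width_sigma": 1.5,
        "w_ee": 0.2,
        "w_ei": 1.0,
        "w_ie": 300.0,
        "sigma_e": 3.0,                # E->E / E->I coupling spread (px)
        "sigma_i": 50.0,               # I->E coupling spread (px)
        "dt": 0.5,
        "n_steps": 40,
        "sat_ceiling": 1.0,            # S(x) = clip(x, 0, ceiling)
        "divergence_bound": 1e6,
        "readout_half_width": 64,      # px, readout window around the target
        "train_category": "squares",
    },
    "v1": {
        "n_orient": 12,
        "grid_stride": 4,
        "filter_sigma_long": 6.0,
        "filter_sigma_short": 1.5,
        "filter_surround": 2.5,        # surround sigma factor for zero-mean
        "J": {"reach": 6, "angle_tol_deg": 25.0, "gain": 0.6},
        "W": {"reach": 4, "gain": 1.2},
        "leak": 1.0,
        "dt": 0.5,
        "n_steps": 12,
        "sat_ceiling": 2.0,
        "divergence_bound": 1e6,
    },
    "fourier": {
        "max_width": 8,                # radial bins per pass-band
        "default_band": [2, 10],       # used when scoring without a search
        "xcorr_max_shift": 0,
    },
    "grouping": {
        "segment_length": 10,
        "n_orient": 8,
        "gap_max": 12.0,               # illusory-contour endpoint gap (px)
        "angle_tol_deg": 22.5,
        "lateral_tol": 3.0,            # collinearity: lateral offset bound
        "sigma": 48.0,                 # selection-signal positional scatter
        "footprint_radius": 48.0,      # spatial extent of a selection signal
        "n_signals": 1,
        "n_trials": 20,
        "candidate_stride": 16,        # seed-center tuning grid
        "tune_samples": 200,
        "sigma_base": 0.4,             # px, baseline offset jitter
        "interference_gain": 1.5,      # jitter per unit of weighted clutter
        "interference_sigma": 64.0,    # spatial falloff of clutter weight
    },
    "bench": {
        "rel_margin": 0.10,
        "n_replicates": 3,             # stochastic (grouping) cells
        "many_flankers": 7,
    },
}


def default_config() -> dict:
    """A deep copy of the shipped defaults."""
    return copy.deepcopy(DEFAULTS)


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Load defaults, optionally deep-merged with a YAML override file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, overrides)
    return cfg
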