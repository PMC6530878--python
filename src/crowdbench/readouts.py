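"""Linking hypotheses: from model outputs to performance numbers.

Four readouts are implemented, all monotone in the underlying model output
so that none of them can turn a monotone performance profile into a
U-shaped one (or vice versa):

* ``lr_difference`` — total absolute difference between the normalized
  left- and right-offset output images (higher = easier discrimination);
* ``template_xcorr`` — peak normalized cross-correlation with the
  vernier-alone output, maximized over small spatial shifts;
* ``to_threshold`` / ``fit_psychometric`` — monotone-decreasing maps from
  raw output to a human-threshold-like scale (a simple reciprocal, or a
  power law fitted in log-log space on one training category);
* ``train_decoder`` — a left/right classifier (one 512-unit hidden layer,
  softmax output) on z-scored feature vectors, optionally with a sparse
  readout that keeps only a fixed random subset of the features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

#: Fraction of features kept by the sparse readout (75% of units dropped).
SPARSE_RETAIN_FRAC = 0.25


@dataclass(frozen=True)
class RawScore:
    """Raw model output; higher = easier discrimination."""
    value: float
    kind: str  # {"lr_difference", "xcorr", "decoder_accuracy"}

    def __post_init__(self):
        if self.value < -1e-12:
            raise ValueError("raw scores are nonnegative")


@dataclass(frozen=True)
class ThresholdLike:
    """Performance on the human-threshold scale; lower = better."""
    value: float

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError("threshold-like values are positive")


@dataclass(frozen=True)
class PsychometricFit:
    """Power-law map t(c) = a * c**b, fitted in log-log space; b < 0 for a
    well-behaved (monotone-decreasing) threshold readout."""
    a: float
    b: float
    train_category: str = ""


# ---------------------------------------------------------------------------

def lr_difference(left: np.ndarray, right: np.ndarray) -> RawScore:
    """Sum of absolute differences between unit-sum-normalized outputs.

    Both maps are normalized to unit total intensity first, so the score is
    invariant to global intensity scaling and lies in [0, 2].
    """
    left = np.abs(np.asarray(left, dtype=float))
    right = np.abs(np.asarray(right, dtype=float))
    if left.shape != right.shape:
        raise ValueError("shape mismatch")
    ls, rs = left.sum(), right.sum()
    if ls == 0 or rs == 0:
        raise ValueError("all-zero image: normalization undefined")
    value = float(np.abs(left / ls - right / rs).sum())
    return RawScore(value=value, kind="lr_difference")


def _norm_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / (na * nb))


def template_xcorr(out, reference, max_shift: int = 2,
                   reduce: str = "sum") -> RawScore:
    """Peak normalized cross-correlation with the vernier-alone reference.

    ``out`` and ``reference`` are 2-D maps or (channel, H, W) stacks.  Per
    channel (``reduce="sum"``) or over the concatenated channels
    (``reduce="joint"``), the correlation is mean-removed, norm-divided and
    maximized over spatial shifts within ``±max_shift`` px.  Zero-variance
    maps score 0 (logged).
    """
    out = np.asarray(out, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if out.ndim == 2:
        out = out[None]
    if ref.ndim == 2:
        ref = ref[None]
    if out.shape != ref.shape:
        raise ValueError("shape mismatch between output and reference")
    if not np.any(ref):
        raise ValueError("reference is all zero")

    shifts = range(-max_shift, max_shift + 1)

    def peak(a: np.ndarray, b: np.ndarray) -> float:
        best = -np.inf
        for dy in shifts:
            rolled = np.roll(a, dy, axis=-2)
            for dx in shifts:
                best = max(best, _norm_xcorr(np.roll(rolled, dx, axis=-1), b))
        return best

    if reduce == "joint":
        value = peak(out, ref)
    elif reduce == "sum":
        value = 0.0
        for c in range(out.shape[0]):
            if np.ptp(out[c]) == 0 or np.ptp(ref[c]) == 0:
                logger.info("zero-variance channel %d scored 0", c)
                continue
            value += peak(out[c], ref[c])
    else:
        raise ValueError("reduce must be 'sum' or 'joint'")
    return RawScore(value=max(value, 0.0), kind="xcorr")


def to_threshold(raw: RawScore | float, scale: float = 1.0,
                 ceiling: float = 1e6) -> ThresholdLike:
    """Monotone transform raw -> threshold-like: scale / raw (lower = better)."""
    value = raw.value if isinstance(raw, RawScore) else float(raw)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if value <= 0:
        logger.warning("raw score %.3g <= 0; returning ceiling %.3g", value, ceiling)
        return ThresholdLike(value=ceiling)
    return ThresholdLike(value=scale / value)


def fit_psychometric(raw_scores, human_thresholds,
                     train_category: str = "") -> PsychometricFit:
    """Least-squares fit of log t = log a + b log c on >= 3 training pairs."""
    c = np.asarray([r.value if isinstance(r, RawScore) else float(r)
                    for r in raw_scores], dtype=float)
    t = np.asarray([x.value if isinstance(x, ThresholdLike) else float(x)
                    for x in human_thresholds], dtype=float)
    if c.size < 3 or t.size != c.size:
        raise ValueError("need at least 3 (raw, threshold) training pairs")
    if np.any(c <= 0) or np.any(t <= 0):
        raise ValueError("raw scores and thresholds must be positive")
    b, loga = np.polyfit(np.log(c), np.log(t), 1)
    if b >= 0:
        warnings.warn("fitted exponent b >= 0: readout does not behave like "
                      "a threshold", stacklevel=2)
    return PsychometricFit(a=float(np.exp(loga)), b=float(b),
                           train_category=train_category)


def apply_psychometric(fit: PsychometricFit, raw: RawScore | float) -> ThresholdLike:
    value = raw.value if isinstance(raw, RawScore) else float(raw)
    if value <= 0:
        raise ValueError("raw score must be positive")
    return ThresholdLike(value=float(fit.a * value ** fit.b))


# ---------------------------------------------------------------------------
# decoder readout
# ---------------------------------------------------------------------------

@dataclass
class Decoder:
    model: MLPClassifier
    scaler: StandardScaler
    retained: np.ndarray  # feature indices kept by the (possibly sparse) readout

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)[:, self.retained]
        return self.model.predict(self.scaler.transform(X))


def train_decoder(features, labels, hidden_units: int = 512,
                  retain_frac: float = 1.0, seed: int = 0) -> Decoder:
    """Train the left/right offset classifier on per-stimulus feature vectors.

    Features are z-scored; ``retain_frac < 1`` masks a fixed random subset
    of the input features (sampled once with ``seed``) before training and
    testing — the sparse-readout variant.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both left and right labels")
    if not 0 < retain_frac <= 1:
        raise ValueError("retain_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    n_keep = max(1, int(round(retain_frac * n_feat)))
    retained = np.sort(rng.choice(n_feat, size=n_keep, replace=False))
    scaler = StandardScaler().fit(X[:, retained])
    clf = MLPClassifier(hidden_layer_sizes=(hidden_units,), activation="relu",
                        solver="adam", early_stopping=False, max_iter=300,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny data
        clf.fit(scaler.transform(X[:, retained]), y)
    return Decoder(model=clf, scaler=scaler, retained=retained)


def decoder_accuracy(decoder: Decoder, features, labels) -> RawScore:
    y = np.asarray(labels)
    pred = decoder.predict(features)
    return RawScore(value=float(np.mean(pred == y)), kind="decoder_accuracy")
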