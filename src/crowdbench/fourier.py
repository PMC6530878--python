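"""Band-pass Fourier model.

The model band-pass filters each stimulus with an annular mask in the
discrete frequency plane (a small contiguous range of radial frequencies
at all orientations), then measures how similar the filtered stimulus is
to the filtered vernier-alone reference via normalized cross-correlation.
The finite set of pass-bands is searched exhaustively for the band whose
(psychometrically mapped) performance pattern best matches the human
pattern on a training category.

Radial frequency is measured in cycles per image height, so a bin width of
one corresponds to one cycle across the canvas; the search enumerates all
contiguous half-open bins [f_lo, f_hi) up to a maximum width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import default_config
from .readouts import (RawScore, ThresholdLike, apply_psychometric,
                       fit_psychometric, template_xcorr)
from .stimgen import StimulusImage


@dataclass(frozen=True)
class PassBand:
    f_lo: int
    f_hi: int  # half-open [f_lo, f_hi)

    def __post_init__(self):
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError("need 0 <= f_lo < f_hi")

    @property
    def width(self) -> int:
        return self.f_hi - self.f_lo


def radial_bin_grid(shape: tuple[int, int]) -> np.ndarray:
    """Integer radial-frequency bin per FFT coefficient (cycles per image
    height, isotropic in cycles/pixel)."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    return np.floor(np.hypot(fy, fx) * h).astype(int)


def nyquist_bin(shape: tuple[int, int]) -> int:
    """One past the largest radial bin present for this image size; the full
    band [0, nyquist_bin) passes the whole spectrum."""
    return int(radial_bin_grid(shape).max()) + 1


def enumerate_bands(nyquist: int, max_width: int) -> list[PassBand]:
    """All contiguous bands [i, j) with width <= max_width, deterministic
    order (by f_lo, then width)."""
    if max_width < 1:
        raise ValueError("max_width must be >= 1")
    bands = []
    for lo in range(nyquist):
        for hi in range(lo + 1, min(lo + max_width, nyquist) + 1):
            bands.append(PassBand(lo, hi))
    bands.sort(key=lambda b: (b.f_lo, b.width))
    return bands


def band_mask(shape: tuple[int, int], band: PassBand) -> np.ndarray:
    bins = radial_bin_grid(shape)
    return (bins >= band.f_lo) & (bins < band.f_hi)


def bandpass(image: StimulusImage | np.ndarray, band: PassBand) -> np.ndarray:
    """Annular frequency mask applied to the image (linear operator)."""
    img = image.pixels if isinstance(image, StimulusImage) else np.asarray(image, float)
    spectrum = np.fft.fft2(img)
    return np.real(np.fft.ifft2(spectrum * band_mask(img.shape, band)))


def _masked_amplitude(img: np.ndarray, band: PassBand) -> np.ndarray:
    """Amplitude spectrum of the band-passed image.

    Equals ``|fft2(bandpass(img, band))|``; computed directly from the
    stimulus spectrum so that band searches need no inverse transforms.
    """
    return np.abs(np.fft.fft2(img)) * band_mask(img.shape, band)


def fourier_score(pair, reference_pair, band: PassBand,
                  max_shift: int = 0) -> RawScore:
    """Normalized correlation between the band-limited amplitude spectra of
    the stimulus and the vernier-alone reference, averaged over the
    left/right offset versions.  A band that passes no stimulus energy
    scores 0."""
    values = []
    for img, ref in zip(pair, reference_pair):
        a = _masked_amplitude(_pixels(img), band)
        b = _masked_amplitude(_pixels(ref), band)
        if not np.any(a) or not np.any(b):
            values.append(0.0)
            continue
        values.append(max(template_xcorr(a, b, max_shift=max_shift,
                                         reduce="joint").value, 0.0))
    return RawScore(value=float(np.mean(values)), kind="xcorr")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, StimulusImage) else np.asarray(img, float)


def select_band(band_scores: dict[PassBand, tuple[float, float, float]],
                human_triplet: tuple[float, float, float]) -> PassBand:
    """Pick the pass-band whose performance pattern best matches humans.

    ``band_scores`` maps each band to the raw-score triplet (vernier alone,
    1 flanker, many flankers) for the training category; for each band a
    psychometric power law is fitted to the human triplet and the band
    minimizing the squared threshold error is returned.  Deterministic
    tie-break: lowest f_lo, then narrowest band.
    """
    if not band_scores:
        raise ValueError("no candidate bands")
    human = np.asarray(human_triplet, dtype=float)
    if human.size != 3 or np.any(human <= 0):
        raise ValueError("human pattern must be 3 positive thresholds")
    best: tuple[float, int, int] | None = None
    best_band: PassBand | None = None
    for band in sorted(band_scores, key=lambda b: (b.f_lo, b.width)):
        raws = np.asarray(band_scores[band], dtype=float)
        if np.any(raws <= 0):
            continue
        fit = fit_psychometric(raws, human)
        pred = np.array([apply_psychometric(fit, float(c)).value for c in raws])
        sse = float(np.sum((pred - human) ** 2))
        key = (sse, band.f_lo, band.width)
        if best is None or key < best:
            best, best_band = key, band
    if best_band is None:
        raise ValueError("no band produced positive scores")
    return best_band


def score_triplet_for_band(db, category: str, band: PassBand,
                           max_shift: int = 0) -> tuple[float, float, float]:
    """Raw-score triplet (alone, one, many) of one category under one band."""
    ids = db.triplet_ids(category)
    ref = db.condition(ids[0])
    return tuple(fourier_score(db.condition(cid), ref, band,
                               max_shift=max_shift).value for cid in ids)


def search_bands(db, category: str, config: dict | None = None,
                 max_shift: int | None = None) -> dict[PassBand, tuple[float, float, float]]:
    """Raw-score triplets for every enumerable band on one category.

    Stimulus spectra are computed once; each band then only masks them.
    """
    cfg = (config or default_config())["fourier"]
    if max_shift is None:
        max_shift = cfg["xcorr_max_shift"]
    ids = db.triplet_ids(category)
    shape = _pixels(db.condition(ids[0])[0]).shape
    bands = enumerate_bands(nyquist_bin(shape), cfg["max_width"])

    amps = {cid: [np.abs(np.fft.fft2(_pixels(img)))
                  for img in db.condition(cid)] for cid in ids}
    bins = radial_bin_grid(shape)
    out: dict[PassBand, tuple[float, float, float]] = {}
    for band in bands:
        mask = (bins >= band.f_lo) & (bins < band.f_hi)
        triplet = []
        for cid in ids:
            vals = []
            for side in (0, 1):
                a = amps[cid][side] * mask
                b = amps[ids[0]][side] * mask
                if not np.any(a) or not np.any(b):
                    vals.append(0.0)
                else:
                    vals.append(max(template_xcorr(a, b, max_shift=max_shift,
                                                   reduce="joint").value, 0.0))
            triplet.append(float(np.mean(vals)))
        out[band] = tuple(triplet)
    return out
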