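"""Wilson-Cowan-type two-layer recurrent field with end-stopped front end.

Pipeline per stimulus: a difference-of-Gaussians LGN stage, a bank of three
vertically oriented end-stopped receptive fields (preferred bar lengths:
one vernier bar, the whole vernier, the flanker size), and, per channel, a
reciprocally coupled excitatory/inhibitory field iterated with a forward
Euler scheme:

    E <- E + dt * (-E + S(F + w_ee * G_e*E - w_ie * G_i*I))
    I <- I + dt * (-I + S(w_ei * G_e*E))

with a rectified-saturating nonlinearity S(x) = clip(x, 0, ceiling) and
Gaussian coupling kernels (narrow for excitation, wide for inhibition).
The wide inhibitory pool makes the network suppress spatially repeated
structure more than isolated structure — the discontinuity-detector
behaviour that lets a regular row of flankers be suppressed while the
vernier survives.

Performance: the stabilized excitatory maps of the three channels are
cross-correlated with the vernier-alone maps and the three correlations
are summed into one raw score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .config import default_config
from .readouts import RawScore, template_xcorr
from .stimgen import StimulusImage


class DivergenceError(RuntimeError):
    """Dynamics left the configured stability bound."""


@dataclass
class WCParams:
    dog_sigma_center: float = 1.2
    dog_sigma_surround: float = 2.4
    dog_gain: float = 20.0
    rf_lengths: tuple[int, int, int] = (20, 42, 48)
    rf_width_sigma: float = 1.5
    w_ee: float = 0.2
    w_ei: float = 1.0
    w_ie: float = 300.0
    sigma_e: float = 3.0
    sigma_i: float = 50.0
    dt: float = 0.5
    n_steps: int = 40
    sat_ceiling: float = 1.0
    divergence_bound: float = 1e6
    readout_half_width: int = 64   # px; Bouma-sized readout window (0 = full)

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        lengths = tuple(self.rf_lengths)
        if len(lengths) != 3 or not (lengths[0] < lengths[1] < lengths[2]):
            raise ValueError("rf_lengths must be exactly 3 strictly "
                             "increasing lengths")
        for s in (self.dog_sigma_center, self.dog_sigma_surround,
                  self.rf_width_sigma, self.sigma_e, self.sigma_i):
            if s <= 0:
                raise ValueError("all sigmas must be positive")

    @classmethod
    def from_config(cls, config: dict | None = None) -> "WCParams":
        cfg = (config or default_config())["wc"]
        return cls(dog_sigma_center=cfg["dog"]["sigma_center"],
                   dog_sigma_surround=cfg["dog"]["sigma_surround"],
                   dog_gain=cfg["dog"]["gain"],
                   rf_lengths=tuple(cfg["rf_lengths"]),
                   rf_width_sigma=cfg["rf_width_sigma"],
                   w_ee=cfg["w_ee"], w_ei=cfg["w_ei"], w_ie=cfg["w_ie"],
                   sigma_e=cfg["sigma_e"], sigma_i=cfg["sigma_i"],
                   dt=cfg["dt"], n_steps=cfg["n_steps"],
                   sat_ceiling=cfg["sat_ceiling"],
                   divergence_bound=cfg["divergence_bound"],
                   readout_half_width=cfg["readout_half_width"])


@dataclass
class WCState:
    E: list[np.ndarray] = field(default_factory=list)  # one map per rf channel
    I: list[np.ndarray] = field(default_factory=list)


def lgn_filter(image: StimulusImage | np.ndarray, params: WCParams) -> np.ndarray:
    """On-center off-surround (difference-of-Gaussians) contrast map."""
    if params.dog_sigma_center >= params.dog_sigma_surround:
        raise ValueError("DoG center sigma must be smaller than surround sigma")
    img = image.pixels if isinstance(image, StimulusImage) else np.asarray(image, float)
    center = gaussian_filter(img, params.dog_sigma_center, mode="constant",
                             truncate=6.0)
    surround = gaussian_filter(img, params.dog_sigma_surround, mode="constant",
                               truncate=6.0)
    return params.dog_gain * (center - surround)


def endstopped_kernel(length: float, width_sigma: float) -> np.ndarray:
    """Vertical end-stopped kernel: elongated excitatory center with
    inhibitory end-zones along the orientation axis; zero total sum.

    The center lobe profile crosses zero near ±length/2, so among bars of
    different lengths the response peaks for a bar matching ``length``.
    """
    sigma_c = length / 4.0
    sigma_e = length / 6.0
    end_at = length / 2.0 + sigma_e
    half = int(np.ceil(end_at + 3 * sigma_e))
    y = np.arange(-half, half + 1, dtype=float)
    center = np.exp(-y ** 2 / (2 * sigma_c ** 2))
    ends = (np.exp(-(y - end_at) ** 2 / (2 * sigma_e ** 2))
            + np.exp(-(y + end_at) ** 2 / (2 * sigma_e ** 2)))
    ends *= center.sum() / ends.sum()          # zero total sum
    profile = center - ends
    xhalf = int(np.ceil(3 * width_sigma))
    x = np.arange(-xhalf, xhalf + 1, dtype=float)
    gx = np.exp(-x ** 2 / (2 * width_sigma ** 2))
    gx /= gx.sum()
    kernel = np.outer(profile, gx)
    return kernel / np.abs(kernel).sum()


def endstopped_bank(rf_lengths, width_sigma: float = 1.5) -> list[np.ndarray]:
    lengths = tuple(rf_lengths)
    if len(lengths) != 3 or not (lengths[0] < lengths[1] < lengths[2]):
        raise ValueError("need 3 strictly increasing rf lengths")
    return [endstopped_kernel(L, width_sigma) for L in lengths]


def _drive(image, params: WCParams) -> list[np.ndarray]:
    contrast = lgn_filter(image, params)
    bank = endstopped_bank(params.rf_lengths, params.rf_width_sigma)
    return [np.maximum(fftconvolve(contrast, k, mode="same"), 0.0) for k in bank]


def run_dynamics(inputs: list[np.ndarray], params: WCParams) -> WCState:
    """Euler-iterate the coupled E/I fields for ``n_steps`` steps."""
    sat = lambda x: np.clip(x, 0.0, params.sat_ceiling)  # noqa: E731
    state = WCState()
    for drive in inputs:
        drive = np.asarray(drive, dtype=float)
        if not np.all(np.isfinite(drive)):
            raise ValueError("non-finite input map")
        E = np.zeros_like(drive)
        I = np.zeros_like(drive)
        for _ in range(params.n_steps):
            exc_pool = gaussian_filter(E, params.sigma_e, mode="constant")
            inh_pool = gaussian_filter(I, params.sigma_i, mode="constant")
            E = E + params.dt * (-E + sat(drive + params.w_ee * exc_pool
                                          - params.w_ie * inh_pool))
            I = I + params.dt * (-I + sat(params.w_ei * exc_pool))
            if np.max(np.abs(E)) > params.divergence_bound:
                raise DivergenceError(
                    f"excitatory activity exceeded {params.divergence_bound:g}")
        state.E.append(E)
        state.I.append(I)
    return state


def wc_response(image, params: WCParams | None = None) -> WCState:
    """Full front-end + dynamics for one stimulus image."""
    params = params or WCParams()
    return run_dynamics(_drive(image, params), params)


def _readout_crop(maps: np.ndarray, half_width: int) -> np.ndarray:
    """Crop channel maps to a column window centred on the target.

    The vernier-offset readout assesses the target representation, so the
    correlation is taken over a Bouma-window-sized region around the
    vernier rather than the full canvas (otherwise remote flankers merely
    dilate the normalization without carrying target information).
    """
    if half_width <= 0:
        return maps
    w = maps.shape[-1]
    lo = max(w // 2 - half_width, 0)
    return maps[..., lo:w // 2 + half_width]


def wc_score(pair: tuple[StimulusImage, StimulusImage],
             reference: tuple[WCState, WCState],
             params: WCParams | None = None,
             max_shift: int = 2) -> RawScore:
    """Sum over the three end-stopped channels of the peak normalized
    cross-correlation with the vernier-alone run; averaged over the
    left/right offset versions."""
    params = params or WCParams()
    values = []
    for img, ref_state in zip(pair, reference):
        state = wc_response(img, params)
        score = template_xcorr(
            _readout_crop(np.stack(state.E), params.readout_half_width),
            _readout_crop(np.stack(ref_state.E), params.readout_half_width),
            max_shift=max_shift, reduce="sum")
        values.append(score.value)
    return RawScore(value=float(np.mean(values)), kind="xcorr")


def wc_reference(vernier_pair: tuple[StimulusImage, StimulusImage],
                 params: WCParams | None = None) -> tuple[WCState, WCState]:
    params = params or WCParams()
    return tuple(wc_response(img, params) for img in vernier_pair)


def export_channel_pngs(state: WCState, out_dir, prefix: str = "wc") -> list:
    """Write the per-channel excitatory maps as 8-bit PNGs for inspection."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, E in enumerate(state.E):
        peak = E.max() or 1.0
        arr = np.clip(E / peak * 255.0, 0, 255).astype(np.uint8)
        path = out / f"{prefix}_channel{c}.png"
        Image.fromarray(arr, mode="L").save(path)
        paths.append(path)
    return paths
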