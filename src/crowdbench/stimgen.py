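"""Deterministic generator of the vernier + flanker stimulus battery.

The canonical database holds 40 conditions spanning 11 categories
(circles, Gestalts, hexagons, irregular1, irregular2, lines, octagons,
patternIrregular, patternStars, squares, stars).  Every condition exists in
a left-offset and a right-offset version; every category contains a
vernier-alone, a single-flanker and a many-flanker condition, which is the
triplet the bench module classifies.

Images are binary (background 0, strokes 1), rendered without
anti-aliasing so that pixel-count oracles are exact.  Coordinates are
row-major with the origin at the top-left; "left offset" shifts the lower
vernier bar toward smaller x.  The mirror axis of the stimulus runs
vertically through the upper vernier bar, so for symmetric flanker layouts
``np.fliplr`` maps the left-offset image exactly onto the right-offset one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle

from .config import default_config

#: Canonical category names, fixed order.
CATEGORIES: tuple[str, ...] = (
    "circles", "Gestalts", "hexagons", "irregular1", "irregular2",
    "lines", "octagons", "patternIrregular", "patternStars",
    "squares", "stars",
)

#: Shapes that enclose the central vernier and may occupy the central slot.
_ENCLOSING = {"square", "circle", "hexagon", "octagon",
              "irregular1", "irregular2", "gestalt_composite"}


class SizingError(ValueError):
    """Geometry does not fit the canvas or elements overlap."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VernierGeometry:
    bar_length: int
    bar_width: int
    vertical_gap: int
    offset: int
    offset_dir: str = "left"

    def __post_init__(self):
        if self.bar_length <= 0 or self.bar_width < 1:
            raise ValueError("bar_length must be > 0 and bar_width >= 1")
        if self.vertical_gap < 0 or self.offset < 0:
            raise ValueError("vertical_gap and offset must be >= 0")
        if self.offset_dir not in ("left", "right"):
            raise ValueError("offset_dir must be 'left' or 'right'")


@dataclass(frozen=True)
class FlankerSpec:
    shape: str
    size: int
    count: int
    spacing: int
    layout: str = "row"                 # "row" | "grid3x7"
    central_row_shift: int = 0
    mix: str | None = None              # second shape for mixed grids

    def __post_init__(self):
        if self.layout not in ("row", "grid3x7"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "row" and self.count not in (0, 1, 3, 5, 7):
            raise ValueError("row layouts require count in {0,1,3,5,7}")
        if self.count and self.spacing <= self.size and self.shape != "gestalt_composite":
            raise SizingError("spacing must exceed element size (no overlap)")


@dataclass(frozen=True)
class StimulusSpec:
    category: str
    vernier: VernierGeometry
    flankers: FlankerSpec
    canvas: tuple[int, int]
    px_per_deg: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class StimulusImage:
    """A luminance canvas plus condition metadata.

    ``vernier_pixels`` / ``flanker_pixels`` keep the two layers separate so
    that downstream modules (grouping, templates) can tell target ink from
    flanker ink without re-rendering.
    """
    pixels: np.ndarray
    spec: StimulusSpec | None = None
    label: str | None = None            # "left" | "right"
    vernier_pixels: np.ndarray | None = None
    flanker_pixels: np.ndarray | None = None

    def __post_init__(self):
        p = self.pixels
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class StimulusSet:
    entries: dict[str, tuple[StimulusImage, StimulusImage]]
    manifest: list[dict] = field(default_factory=list)

    def categories(self) -> list[str]:
        return sorted({m["category"] for m in self.manifest})

    def condition(self, cond_id: str) -> tuple[StimulusImage, StimulusImage]:
        return self.entries[cond_id]

    def triplet_ids(self, category: str) -> tuple[str, str, str]:
        """Condition ids for the (alone, one flanker, many flankers) triplet."""
        roles = {m["role"]: m["condition_id"] for m in self.manifest
                 if m["category"] == category and m["role"] in ("alone", "one", "many")}
        return roles["alone"], roles["one"], roles["many"]

    def export_png(self, out_dir: str | Path) -> list[Path]:
        """8-bit grayscale PNG per image plus a JSON manifest; deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for cond_id, (left, right) in sorted(self.entries.items()):
            for img, tag in ((left, "left"), (right, "right")):
                path = out / f"{cond_id.replace('/', '_')}_{tag}.png"
                arr = (img.pixels * 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(path)
                written.append(path)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        written.append(manifest_path)
        return written


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _canvas_center(canvas: tuple[int, int]) -> tuple[float, float]:
    # mirror axis between columns W/2-1 and W/2 => center col W/2 - 0.5
    h, w = canvas
    return h / 2.0, w / 2.0 - 0.5


def render_vernier(geom: VernierGeometry, canvas: tuple[int, int]) -> StimulusImage:
    """Render the two vernier bars; the lower bar is displaced by ``offset``."""
    h, w = canvas
    cy, cx = _canvas_center(canvas)
    L, bw, g, o = geom.bar_length, geom.bar_width, geom.vertical_gap, geom.offset
    top = int(round(cy)) - (2 * L + g) // 2
    col0 = int(cx - bw / 2.0 + 0.5)     # leftmost column of the upper bar
    shift = -o if geom.offset_dir == "left" else o
    if top < 0 or top + 2 * L + g > h or col0 + shift < 0 or col0 + bw + abs(shift) > w:
        raise SizingError("vernier geometry exceeds canvas")
    img = np.zeros((h, w), dtype=np.float32)
    img[top:top + L, col0:col0 + bw] = 1.0
    img[top + L + g:top + 2 * L + g, col0 + shift:col0 + bw + shift] = 1.0
    return StimulusImage(pixels=img, label=geom.offset_dir,
                         vernier_pixels=img.copy(),
                         flanker_pixels=np.zeros_like(img))


def _regular_polygon(n: int, radius: float, phase_deg: float) -> list[tuple[float, float]]:
    ang = np.deg2rad(phase_deg + 360.0 * np.arange(n) / n)
    return list(zip(radius * np.cos(ang), -radius * np.sin(ang)))


def _star_vertices(radius: float, n_points: int = 5,
                   inner_frac: float = 0.45) -> list[tuple[float, float]]:
    verts = []
    for k in range(2 * n_points):
        r = radius if k % 2 == 0 else inner_frac * radius
        a = np.deg2rad(90.0 + 180.0 * k / n_points)
        verts.append((r * np.cos(a), -r * np.sin(a)))
    return verts


def _closed(verts: list[tuple[float, float]]) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    return [(verts[i], verts[(i + 1) % len(verts)]) for i in range(len(verts))]


def _irregular1_segments(size: float, rng: np.random.Generator):
    """Jittered polygon with vertical 'chimneys' abutting the vernier tips.

    The chimney edges are near-vertical segments a few pixels above/below the
    vernier bar tips; with the default contour-linking tolerances they form
    illusory contours with the vernier, reproducing configurations whose
    flankers group with the target.
    """
    h = size / 2.0
    c = h / 24.0                         # drawn for size 48, scaled otherwise
    base = [
        (2 * c, -34 * c), (2 * c, -24 * c),      # right chimney edge (top)
        (8 * c, -24 * c), (20 * c, -16 * c), (24 * c, -4 * c),
        (22 * c, 10 * c), (12 * c, 22 * c),
        (2 * c, 24 * c), (2 * c, 34 * c),        # right chimney edge (bottom)
        (-2 * c, 34 * c), (-2 * c, 24 * c),
        (-14 * c, 21 * c), (-23 * c, 8 * c), (-24 * c, -6 * c),
        (-16 * c, -18 * c), (-8 * c, -24 * c),
        (-2 * c, -24 * c), (-2 * c, -34 * c),
    ]
    jittered = []
    for (x, y) in base:
        if abs(x) <= 2 * c + 1e-6:       # keep chimney edges exact
            jittered.append((x, y))
        else:
            jittered.append((x + rng.uniform(-2, 2), y + rng.uniform(-2, 2)))
    return _closed(jittered)


def _irregular2_segments(size: float, rng: np.random.Generator):
    """Jittered decagon with radial-outward jitter (always encloses the vernier)."""
    h = size / 2.0
    verts = []
    for k in range(10):
        a = np.deg2rad(18.0 + 36.0 * k)
        r = h + rng.uniform(0.0, 4.0)
        verts.append((r * np.cos(a), -r * np.sin(a)))
    return _closed(verts)


def _gestalt_segments(size: float):
    """Cuboid wireframe with hidden lines removed (composite line drawing)."""
    h = size / 2.0
    d = size * 10.0 / 48.0               # oblique-projection depth
    front = _closed([(-h, -h), (h, -h), (h, h), (-h, h)])
    extras = [
        ((-h + d, -h - d), (h + d, -h - d)),     # back top edge
        ((h + d, -h - d), (h + d, h - d)),       # back right edge
        ((-h, -h), (-h + d, -h - d)),            # top-left diagonal
        ((h, -h), (h + d, -h - d)),              # top-right diagonal
        ((h, h), (h + d, h - d)),                # bottom-right diagonal
    ]
    return front + extras


def _shape_segments(shape: str, size: float, rng: np.random.Generator | None):
    h = size / 2.0
    if shape == "square":
        return _closed([(-h, -h), (h, -h), (h, h), (-h, h)])
    if shape == "circle":
        return _closed(_regular_polygon(48, h, 90.0))
    if shape == "hexagon":
        return _closed(_regular_polygon(6, h, 90.0))      # pointy-top
    if shape == "octagon":
        return _closed(_regular_polygon(8, h, 90.0))      # vertex-top
    if shape == "star":
        return _closed(_star_vertices(h))
    if shape == "line":
        return [((0.0, -h), (0.0, h))]
    if shape == "irregular1":
        return _irregular1_segments(size, rng or np.random.default_rng(0))
    if shape == "irregular2":
        return _irregular2_segments(size, rng or np.random.default_rng(0))
    if shape == "gestalt_composite":
        return _gestalt_segments(size)
    raise ValueError(f"unknown flanker shape {shape!r}")


def _raster_segments(segments, center_yx: tuple[float, float],
                     canvas: tuple[int, int], stroke_width: int = 1) -> np.ndarray:
    h, w = canvas
    cy, cx = center_yx
    img = np.zeros((h, w), dtype=np.float32)
    for (x0, y0), (x1, y1) in segments:
        r0, c0 = int(round(cy + y0)), int(round(cx + x0))
        r1, c1 = int(round(cy + y1)), int(round(cx + x1))
        for r, c in ((r0, c0), (r1, c1)):
            if not (0 <= r < h and 0 <= c < w):
                raise SizingError("flanker segment exceeds canvas")
        rr, cc = draw_line(r0, c0, r1, c1)
        img[rr, cc] = 1.0
    if stroke_width > 1:
        img = dilation(img, footprint_rectangle((stroke_width, stroke_width)))
    return img


def _row_slots(shape: str, count: int) -> list[int]:
    """Slot indices for a row layout (slot 0 surrounds the vernier).

    Shapes that cannot enclose the vernier (lines, stars) skip the central
    slot and use symmetric side slots instead.
    """
    if count == 0:
        return []
    if shape in _ENCLOSING:
        k = (count - 1) // 2
        return list(range(-k, k + 1))
    k = (count + 1) // 2
    return [s for s in range(-k, k + 1) if s != 0]


def render_flankers(spec: StimulusSpec,
                    rng: np.random.Generator | None = None,
                    stroke_width: int = 1,
                    symmetrize: bool | None = None) -> StimulusImage:
    """Render the flanker layer only (no vernier).

    Row layouts are centered on the vernier position; for enclosing shapes
    the central slot is occupied by the innermost flanker.  Overlapping
    elements raise :class:`SizingError`.  When the layout is left/right
    symmetric the rendered image is exactly mirror-symmetric about the
    vernier axis (sub-pixel rounding is healed by unioning with the mirror).
    """
    fl = spec.flankers
    canvas = spec.canvas
    cy, cx = _canvas_center(canvas)
    if symmetrize is None:
        symmetrize = fl.shape != "gestalt_composite" and fl.central_row_shift == 0

    placements: list[tuple[str, float, float, float]] = []  # shape, x, y, size
    if fl.layout == "row":
        for s in _row_slots(fl.shape, fl.count):
            placements.append((fl.shape, s * fl.spacing, 0.0, float(fl.size)))
    else:  # grid3x7: 21 slots; central slot takes the mix shape (enclosing)
        if fl.count not in (0, 1, 21):
            raise ValueError("grid3x7 supports count in {0, 1, 21}")
        from .config import DEFAULTS
        central_shape = fl.mix or fl.shape
        el_size = float(DEFAULTS["stimuli"]["grid_element_size"])
        if fl.count >= 1:
            placements.append((central_shape, float(fl.central_row_shift), 0.0,
                               float(fl.size)))
        if fl.count == 21:
            row_sp = DEFAULTS["stimuli"]["grid_row_spacing"]
            for row in (-1, 0, 1):
                for col in range(-3, 4):
                    if row == 0 and col == 0:
                        continue
                    dx = col * fl.spacing + (fl.central_row_shift if row == 0 else 0)
                    placements.append((fl.shape, float(dx), float(row * row_sp),
                                       el_size))

    img = np.zeros(canvas, dtype=np.float32)
    for shape, dx, dy, size in placements:
        el = _raster_segments(_shape_segments(shape, size, rng),
                              (cy + dy, cx + dx), canvas, stroke_width)
        if np.any((img > 0) & (el > 0)):
            raise SizingError("adjacent flankers overlap")
        img = np.maximum(img, el)
    if symmetrize:
        img = np.maximum(img, img[:, ::-1])
    return StimulusImage(pixels=img, spec=spec,
                         vernier_pixels=np.zeros_like(img),
                         flanker_pixels=img.copy())


def compose(vernier: StimulusImage, flankers: StimulusImage) -> StimulusImage:
    """Pixelwise maximum of the two layers; metadata merged."""
    if vernier.pixels.shape != flankers.pixels.shape:
        raise ValueError("canvas shapes differ")
    out = np.maximum(vernier.pixels, flankers.pixels)
    return StimulusImage(
        pixels=out,
        spec=flankers.spec or vernier.spec,
        label=vernier.label or flankers.label,
        vernier_pixels=(vernier.vernier_pixels if vernier.vernier_pixels is not None
                        else vernier.pixels.copy()),
        flanker_pixels=(flankers.flanker_pixels if flankers.flanker_pixels is not None
                        else flankers.pixels.copy()),
    )


def bouma_window(eccentricity: float) -> float:
    """Classical crowding-zone size: half the eccentricity (both in degrees)."""
    if eccentricity < 0:
        raise ValueError("eccentricity must be >= 0")
    return 0.5 * eccentricity


# ---------------------------------------------------------------------------
# database build
# ---------------------------------------------------------------------------

_CATEGORY_SHAPES = {
    "circles": "circle",
    "Gestalts": "gestalt_composite",
    "hexagons": "hexagon",
    "irregular1": "irregular1",
    "irregular2": "irregular2",
    "lines": "line",
    "octagons": "octagon",
    "squares": "square",
    "stars": "star",
    # grids: (element shape, central shape)
    "patternStars": ("star", "square"),
    "patternIrregular": ("irregular2", "square"),
}


def _category_conditions(category: str) -> list[dict]:
    """Condition plan: role in {alone, one, many, extra} per category."""
    plan = [
        {"suffix": "0", "count": 0, "role": "alone", "optional": False},
        {"suffix": "1", "count": 1, "role": "one", "optional": False},
    ]
    if category in ("patternStars", "patternIrregular"):
        plan.append({"suffix": "21", "count": 21, "role": "many", "optional": False})
        plan.append({"suffix": "21-shift", "count": 21, "role": "extra",
                     "optional": True, "central_row_shift": 16})
    else:
        plan.append({"suffix": "7", "count": 7, "role": "many", "optional": False})
    extras = {"squares": (3, 5), "lines": (3, 5), "circles": (3,)}
    for count in extras.get(category, ()):
        plan.append({"suffix": str(count), "count": count, "role": "extra",
                     "optional": True})
    return plan


def build_database(config: dict | None = None) -> StimulusSet:
    """Build the canonical 40-condition database over the 11 categories.

    Deterministic: the same config yields bit-identical images.  Irregular
    shapes are generated from ``stimuli.irregular_seed`` (recorded in the
    manifest).
    """
    cfg = (config or default_config())["stimuli"]
    canvas = tuple(cfg["canvas"])
    vp = cfg["vernier"]
    seed = int(cfg["irregular_seed"])
    entries: dict[str, tuple[StimulusImage, StimulusImage]] = {}
    manifest: list[dict] = []

    verniers = {
        d: render_vernier(VernierGeometry(vp["bar_length"], vp["bar_width"],
                                          vp["vertical_gap"], vp["offset"], d),
                          canvas)
        for d in ("left", "right")
    }

    for cat_index, category in enumerate(CATEGORIES):
        shape_entry = _CATEGORY_SHAPES[category]
        grid = isinstance(shape_entry, tuple)
        for cond in _category_conditions(category):
            cond_id = f"{category}/{cond['suffix']}"
            if grid:
                shape, mix = shape_entry
                fspec = FlankerSpec(shape=shape, size=cfg["flanker_size"],
                                    count=cond["count"],
                                    spacing=cfg["flanker_spacing"],
                                    layout="grid3x7",
                                    central_row_shift=cond.get("central_row_shift", 0),
                                    mix=mix)
            else:
                spacing = (cfg["gestalt_spacing"] if category == "Gestalts"
                           else cfg["flanker_spacing"])
                fspec = FlankerSpec(shape=shape_entry, size=cfg["flanker_size"],
                                    count=cond["count"], spacing=spacing)
            pair = []
            for d in ("left", "right"):
                sspec = StimulusSpec(
                    category=category,
                    vernier=VernierGeometry(vp["bar_length"], vp["bar_width"],
                                            vp["vertical_gap"], vp["offset"], d),
                    flankers=fspec, canvas=canvas,
                    px_per_deg=cfg["px_per_deg"])
                # irregular vertex jitter: one fixed stream per category so
                # that every condition of a category uses identical outlines
                rng = np.random.default_rng(seed + 1000 * cat_index)
                flank = render_flankers(sspec, rng=rng,
                                        stroke_width=cfg["stroke_width"])
                if np.any((flank.pixels > 0) & (verniers[d].pixels > 0)):
                    raise SizingError(f"{cond_id}: flankers overlap the vernier")
                img = compose(verniers[d], flank)
                img.spec = sspec
                img.label = d
                pair.append(img)
            entries[cond_id] = (pair[0], pair[1])
            manifest.append({
                "condition_id": cond_id,
                "category": category,
                "flanker_count": cond["count"],
                "role": cond["role"],
                "optional": cond["optional"],
                "offset_px": vp["offset"],
                "geometry": {"canvas": list(canvas),
                             "flanker_size": cfg["flanker_size"],
                             "spacing": fspec.spacing,
                             "central_row_shift": fspec.central_row_shift},
                "symmetric": (fspec.shape != "gestalt_composite"
                              and fspec.central_row_shift == 0),
                "irregular_seed": seed,
            })
    return StimulusSet(entries=entries, manifest=manifest)
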