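# Methods

## Stimuli

The canvas is 160×560 px at 32 px/deg (a nominal 4° target eccentricity is
carried as metadata only). The vernier consists of two vertical 20×2 px
bars separated by a 2 px gap; the lower bar is displaced 2 px left or
right. Coordinates are row-major, origin top-left, and "left offset" means
the lower bar moves toward smaller x. The mirror axis runs through the
upper bar, so for left/right-symmetric flanker layouts `np.fliplr` maps the
left-offset image exactly onto the right-offset image; symmetric layouts
are unioned with their mirror after rasterization so this identity is
exact despite rounding.

Flankers are 1-px outlines, default size 48 px, center-to-center spacing
56 px (64 px for the cuboid Gestalt drawings, whose oblique back edges
need wider slots). Shapes that enclose the vernier (squares, circles,
hexagons, octagons, the irregular polygons, cuboids) occupy the central
slot; their row conditions use counts {0,1,3,5,7}. Stars and lines cannot
enclose the vernier without their outlines crossing it, so they occupy
symmetric side slots (the `count` label keeps the same condition levels).
The 3×7 grids (patternStars, patternIrregular) put an enclosing square in
the central slot, 40 px elements elsewhere, row spacing 52 px; the "many"
condition is the full 21-element grid, and a shifted variant moves the
central row by 16 px. Irregular outlines are jittered polygons drawn from
a fixed recorded seed; `irregular1` additionally carries short vertical
"chimney" edges above and below the vernier tips, close and collinear
enough to form illusory contours with the target — the configuration in
which flankers group with the vernier. The canonical database is exactly
40 conditions over 11 categories; every category contributes the
(alone, one, many) triplet the benchmark classifies, and the 7 extra
conditions (intermediate counts, shifted grids) are marked optional in the
manifest.

What the generator emulates: the geometry and configuration logic of the
classic vernier-crowding batteries (flanker larger than target, a single
flanker within Bouma's window, the many-flanker row extending far beyond
it). What it does not: display luminance calibration, exact visual angles
of the original experiments, anti-aliased rendering, and the precise
outlines of the original irregular/Gestalt drawings (ours are seeded
approximations defined in-code). Tests passing on this battery therefore
show that a model reproduces the configural logic of (un)crowding, not
that it fits any specific published threshold.

## Readouts

* `lr_difference`: both output images are normalized to unit total
  intensity and the sum of absolute pixel differences is taken (range
  [0,2]). The outer absolute value is deliberate: without it the integral
  of the signed difference largely cancels, while the quantity is meant to
  measure how *different* the two offset versions are.
* `template_xcorr`: mean-removed, norm-divided correlation against the
  vernier-alone output, maximized over ±2 px shifts (robust to 1-px
  rendering drift). Multi-channel outputs either sum per-channel peaks
  (Wilson–Cowan) or correlate the concatenated channels (V1).
* Threshold transforms: t = scale/raw, or the psychometric power law
  log t = log a + b·log c fitted by least squares on one training
  category (power law chosen as the simplest two-parameter strictly
  monotone family). Monotonicity is the load-bearing property: a readout
  can reverse an ordering but never convert a monotone raw triple into a
  U-shaped threshold triple, so verdicts cannot be artifacts of the
  readout stage (property-tested).
* Decoder: a 512-unit single-hidden-layer ReLU classifier with softmax
  output on z-scored feature vectors (scikit-learn MLP). The sparse
  variant masks a fixed random 75% of input features before training and
  testing.

## Wilson–Cowan field with end-stopped channels

LGN stage: difference of Gaussians (σ_c = 1.2, σ_s = 2.4, gain 20), zero
sum. Three vertical end-stopped kernels with preferred lengths 20/42/48 px
(one bar, whole vernier, flanker): an elongated excitatory center lobe
whose profile crosses zero near ±L/2, flanked by Gaussian end-zones scaled
for zero total sum — the response across bar lengths peaks at the kernel's
own length (brute-force verified). Each channel drives an independent E/I
pair iterated 40 Euler steps (dt = 0.5) with S(x) = clip(x, 0, 1),
narrow excitatory coupling (σ_e = 3 px) and a wide inhibitory pool
(σ_i = 50 px, w_ie = 300 against a mean-normalized Gaussian — i.e. the
inhibition a unit receives tracks the average activity over a
spacing-sized neighborhood).

Two numerical choices matter. First, the operating point: at this gain the
rectification threshold is active, so units whose inhibitory pool roughly
doubles — a flanker with neighbors on both sides — are pushed toward zero
while isolated structure survives. This is the regularity-suppressing
regime: in the 7-square row the central squares inhibit each other and the
vernier's representation recovers; a single square keeps its full response
and masks the target. Second, the readout window: the cross-correlation is
taken over a ±64 px (2°, Bouma-sized) column window around the target,
because the readout assesses the *target's* representation — over the full
canvas, remote flankers only inflate the correlation's normalization
without carrying offset information, which buries the effect the score is
meant to measure. The psychometric fit is trained on the squares category
and applied everywhere else; with these defaults the model uncrowds its
training category and fails to generalize (stars stay crowded), which is
the model's characteristic behaviour, not a target the code enforces.

## V1 recurrent network

Even-symmetric oriented filters (σ_long = 6, σ_short = 1.5, isotropic
surround subtraction for zero mean) at 12 orientations over 180°, rectified
and sampled on a stride-4 grid. Lateral kernels follow association-field
geometry: J > 0 only for near-collinear pairs (orientation difference and
displacement misalignment both within 25°, hard cutoff at twice that,
reach 6 grid units); W > 0 for similarly oriented but non-aligned
(flanking) pairs, ∝ sin²β, reach 4. Both depend only on relative geometry,
hence are translation invariant and exactly rotation equivariant at
representable angles (verified at 90°). The interneuron loop is collapsed
into a direct inhibitory term; 12 Euler steps (dt = 0.5) with a
saturating rectifier. Lateral application is FFT-cached over the
(orientation, y, x) stack for speed. Flankers add response energy and
iso-orientation suppression everywhere, so the correlation with the
vernier-alone output falls monotonically with flanker count: crowding in
every category, uncrowding in none.

## Fourier model

Radial frequency bins of width 1 cycle per image height; pass-bands are all
contiguous half-open bin ranges up to 8 bins wide (884 bands at the default
canvas). Scores correlate the band-masked amplitude spectra of stimulus and
vernier-alone reference — identical to correlating the spectra of
band-passed images, but requiring no inverse transforms during the search.
Band selection fits the psychometric law per band on a training category's
human triplet and minimizes squared threshold error, tie-broken toward the
lowest then narrowest band. Under the defaults the best band for `lines`
differs from the best band for `Gestalts`: band choice does not
generalize across categories, the overfitting signature this model is
included to exhibit.

## Grouping/segmentation model

An algorithmic skeleton of two-stage grouping, not a laminar circuit.
Stage 1: stroke pixels are traced into ≤10 px approximately straight
elements (8-connected growth, turns >45° start a new element); touching
elements link by real adjacency, and near-collinear elements of different
shapes (orientation within 22.5°, endpoint gap ≤ 12 px, lateral offset
≤ 3 px) link by illusory contours. Components of this graph are the
groups: seven squares chain into one wide group through their collinear
horizontal edges; circles, hexagons and stars do not produce collinear
continuations at the default spacing and remain separate — so in this
skeleton uncrowding emerges only for the squares category, a narrower
range than grouping accounts aim for in principle.

Stage 2: per trial, a selection signal (disk footprint of radius 48 px,
center ~ N(tuned center, 48 px)) peels the groups it touches out of the
target layer, unless it also touches the vernier's group or touches
nothing, in which case segmentation fails and everything stays (the
selection then spans the whole stimulus). The tuned center maximizes the
Monte-Carlo probability of successful segmentation over a 16-px candidate
grid with common random numbers (the observer doing the best possible job);
a uniform seed distribution preserves the qualitative ordering, which is
property-tested. Flanker ink remaining near the target interferes with it:
the perceived offset is jittered by zero-mean Gaussian noise whose width
grows with residual flanker contour weighted by a 64-px Gaussian falloff
from the vernier (equivalent-input-noise form of within-group
interference; σ = 0.4 px + 1.5 × weighted-ink ratio). Naive template
matching on a static cluttered layer is *not* degraded by clutter — with a
shared normalization the left/right decision reduces to the sign of
⟨X, T_L − T_R⟩ and flanker ink outside the lower-bar region contributes
exactly zero — so the interference has to act on the target
representation itself, as it does in grouping accounts. The report is then
the template-matched direction of the perceived vernier; performance is the
proportion correct over 20 trials per offset version, deterministic given
the master seed (per-trial substreams). Configurations whose flankers link
to the vernier (irregular1 chimneys) can never be segmented apart and show
no uncrowding.

## Benchmark

For each model and category the (alone, one, many) conditions are scored
against the vernier-alone reference, mapped to thresholds through the
model's designated readout chain, and classified with a 10% relative
margin: crowding iff t₁ > 1.1·t₀; given crowding, uncrowding iff
t_N < 0.9·t₁. The margin guards against float- and trial-noise, is
config-exposed, and is reported with the matrix. Grouping cells average
raw scores over 3 seed replicates and report the replicate spread. Model
failures mark cells not-run with the error recorded. "Many flankers" is
the 7-element condition (21 for grids). The full default benchmark (4
models × 11 categories) runs in a few minutes on one core; problem sizes
(40 recurrent steps on the 160×560 canvas, 12 V1 steps on the stride-4
grid, 884-band searches, 20×3 grouping trials) were chosen as the smallest
at which the qualitative phenomena are stable.

## Known limitations

* The grouping skeleton links only collinear continuations, so it
  under-produces uncrowding relative to full grouping circuits (squares
  only); the linking rule is the natural place to extend it.
* Human reference thresholds are a synthetic relative-valued fixture
  (`crowdbench/data/human_thresholds.yaml`); they anchor psychometric fits
  and band selection but carry no quantitative authority.
* Wilson–Cowan and V1 constants are not taken from the earlier works they
  follow (those constants are not restated there); they are package
  defaults chosen to realize the models' characteristic regimes and are
  fully config-exposed.
* All images are binary and noise-free; contrast- and luminance-dependent
  phenomena are out of scope.
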