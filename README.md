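# crowdbench

Benchmarking models of visual crowding on synthetic vernier stimuli.

In **crowding**, a target becomes hard to identify when other elements are
nearby; in **uncrowding**, *adding* more flankers recovers performance when
they form a configuration that segregates from the target, producing a
U-shaped performance profile over flanker count. Classical local pooling
accounts predict only crowding — uncrowding depends on elements far outside
Bouma's window (≈ 0.5 × eccentricity), which makes it a sharp test for
models of early and mid-level vision.

`crowdbench` regenerates that test from scratch for researchers in visual
psychophysics and computational neuroscience. It provides:

* **A deterministic stimulus generator** — a battery of 40 conditions over 11
  categories (circles, Gestalts, hexagons, irregular1, irregular2, lines,
  octagons, patternIrregular, patternStars, squares, stars). Every condition
  pairs a left-offset and a right-offset vernier (two vertical bars, the
  lower one displaced horizontally), alone or surrounded by 1–7 flanker
  shapes or a 3×7 grid. Images are binary, anti-aliasing off, so pixel-count
  and symmetry oracles are exact.
* **Four models of crowding**
  * `wilson_cowan` — a two-layer excitatory/inhibitory field
    (E′ = −E + S(F + w_ee·G_e∗E − w_ie·G_i∗I), I′ = −I + S(w_ei·G_e∗E))
    behind an LGN difference-of-Gaussians stage and three end-stopped
    receptive-field channels sized to one vernier bar, the whole vernier,
    and the flanker.
  * `v1_saliency` — a recurrent V1 grid of units tuned to 12 orientations
    with association-field lateral connections (collinear excitation J,
    flanking iso-orientation inhibition W).
  * `fourier` — annular band-pass filtering in the frequency plane with an
    exhaustive search over pass-bands.
  * `grouping` — a two-stage contour-grouping/segmentation model: edge
    elements linked by real adjacency and illusory (collinear) contours form
    groups; Gaussian-positioned selection signals peel flanker groups out of
    the target layer over 20 trials per stimulus.
* **Readouts (linking hypotheses)** — left/right difference integrals,
  normalized template cross-correlation against the vernier-alone output,
  the monotone threshold transform t = 1/raw, psychometric power-law fits
  t(c) = a·c^b trained on one category, and a left/right decoder (512-unit
  hidden layer, optional sparse readout keeping 25% of features). All are
  monotone: they can never turn a monotone profile into a U-shape.
* **A benchmark** that classifies every model × category threshold triplet
  (t₀, t₁, t_N) as *crowding-only* (t₁ > t₀, t_N ≥ t₁), *uncrowding*
  (t₁ > t₀, t_N < t₁) or *none*, with a 10% relative margin, and exports the
  verdict grid as CSV/JSON/PNG.

The headline result the package reproduces: **only the grouping model
produces uncrowding consistently**; the recurrent field, V1 and Fourier
models produce crowding but little or no uncrowding.

## Worked example

```python
from crowdbench import build_database, to_threshold
from crowdbench.grouping import GroupingParams, grouping_score

db = build_database()                      # 40 conditions, 11 categories
params = GroupingParams.from_config()
for cond in ("squares/0", "squares/1", "squares/7"):
    score = grouping_score(db.condition(cond), params, seed=1)
    print(cond, round(score.value, 2), round(to_threshold(score).value, 2))
```

prints

```
squares/0 1.0 1.0
squares/1 0.6 1.67
squares/7 0.9 1.11
```

— the vernier alone is reported almost perfectly; a single surrounding
square drops accuracy to 0.60 (crowding: the selection signal can almost
never cover the square without also covering the vernier); seven squares
recover accuracy to 0.90 (uncrowding: the squares link into one wide group
that segments away from the target). On the threshold-like scale this is
the human U-shape. The same triplet under the Wilson–Cowan model with a
psychometric fit trained on squares gives raw cross-correlations
(3.00, 1.47, 1.81) → thresholds (46, 205, 133): uncrowding on its training
category, but none for stars (3.00, 2.79, 2.86) — poor generalization.

`examples/` contains one short script per capability; the CLI wraps the
full pipeline:

```bash
crowdbench build-db --out stimuli/
crowdbench run --models wc,v1,fourier,grouping --out results/
crowdbench report --out results/
```

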