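"""The linking hypotheses: turning model outputs into performance numbers.

All readouts are monotone, so they can reorder a performance profile but
never turn a monotone profile into a U-shape — crowding and uncrowding
cannot be confused by the readout stage.
"""

import numpy as np

from crowdbench import (build_database, fit_psychometric, lr_difference,
                        template_xcorr, to_threshold)

db = build_database()
left, right = db.condition("squares/1")

# 1. left/right difference: how different are the two offset versions?
d = lr_difference(left.pixels, right.pixels)
print(f"lr_difference(squares/1)  = {d.value:.4f}   (in [0, 2]; higher = easier)")

# 2. template cross-correlation against the vernier-alone output
ref_left, _ = db.condition("squares/0")
x = template_xcorr(left.pixels, ref_left.pixels, max_shift=2)
print(f"template_xcorr vs alone   = {x.value:.4f}   (<= 1; higher = easier)")

# 3. threshold-like transform (lower = better, like a human threshold)
t = to_threshold(x)
print(f"threshold-like            = {t.value:.4f}   (= 1/raw)")

# 4. psychometric power law fitted on a training category
raws = np.array([1.0, 0.4, 0.7])          # model raw scores (alone, 1, many)
human = np.array([50.0, 250.0, 100.0])    # human thresholds, same conditions
fit = fit_psychometric(raws, human, train_category="squares")
print(f"psychometric fit: t(c) = {fit.a:.1f} * c^{fit.b:.2f}  "
      "(maps raw output onto the human threshold scale)")
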