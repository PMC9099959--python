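"""Rebalance an imbalanced training set with SMOTE + ENN.

SMOTE interpolates new minority samples between minority nearest
neighbours; ENN then deletes samples whose label disagrees with the
majority vote of their neighbours (boundary noise).
"""

import numpy as np

from toxsig.resampling import ResampleConfig, smote_enn

rng = np.random.default_rng(0)
n_maj, n_min = 450, 50  # imbalance ratio 9
X = np.vstack([
    rng.normal(0.0, 1.0, (n_maj, 10)),
    rng.normal(1.2, 1.0, (n_min, 10)),  # overlapping minority cluster
])
y = np.array([0] * n_maj + [1] * n_min)

Xr, yr = smote_enn(X, y, ResampleConfig(k_smote=5, k_enn=3, seed=0))
print(f"before: {n_maj} inactive / {n_min} active  (IR {n_maj / n_min:.1f})")
print(f"after:  {(yr == 0).sum()} inactive / {(yr == 1).sum()} active  "
      f"(IR {(yr == 0).sum() / (yr == 1).sum():.2f})")
# The minority class is interpolated up to parity and ENN trims ambiguous
# boundary samples from both classes, so a classifier no longer wins by
# predicting 'inactive' everywhere.
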