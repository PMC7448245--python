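"""Fit a Euclidean applicability domain and gate query compounds with it.

The domain threshold is APD = d_bar + Z*sigma (Z = 0.5), computed from the
grand-mean-retained pairwise distances of the z-scored training
descriptors. Queries drawn from the training distribution should fall
in-domain far more often than queries shifted 5 pooled SDs away.
"""

import numpy as np

from multiscreen.applicability import fit_apd, in_domain

rng = np.random.default_rng(1)
train = rng.normal(size=(150, 20))
model = fit_apd(train, z=0.5)
print(f"d_bar={model.d_bar:.3f}  sigma={model.sigma:.3f}  APD={model.apd:.3f}")

same = rng.normal(size=(300, 20))
shifted = rng.normal(size=(300, 20)) + 5.0
rate_same = in_domain(model, same)[0].mean()
rate_shifted = in_domain(model, shifted)[0].mean()
print(f"in-domain rate, training-like queries: {rate_same:.2f}")
print(f"in-domain rate, 5-SD-shifted queries:  {rate_shifted:.2f}")
print("Predictions for out-of-domain compounds are considered unreliable and "
      "are excluded from activity calls.")
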