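"""Where the partition coefficient sees what Pearson and Spearman miss.

Builds a noiseless parabola on a symmetric grid and compares the three
coefficients. Pearson is exactly zero (odd moments vanish), Spearman is
near zero (the relationship is not monotone), while the clustering-based
coefficient pairs the outer x-bins with the high y-bins and scores well
above the noise floor.
"""

import numpy as np
from scipy import stats

from cccoef import FeatureVector, ccc_pair

x = np.linspace(-1.0, 1.0, 200)
y = x ** 2

r = ccc_pair(
    FeatureVector.from_numerical("x", x),
    FeatureVector.from_numerical("y", y),
)
print(f"ccc      = {r.ccc:.3f}  (best partition pair: kx={r.best_kx}, ky={r.best_ky})")
print(f"pearson  = {stats.pearsonr(x, y)[0]:+.3f}")
print(f"spearman = {stats.spearmanr(x, y)[0]:+.3f}")
print()
print("A ccc well above 0 with both classical coefficients at 0 is the")
print("signature of a symmetric nonlinear dependence.")
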