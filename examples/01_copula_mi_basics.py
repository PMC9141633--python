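"""Estimate mutual information with a Gaussian copula.

Draws correlated Gaussian data, estimates MI through the rank-Gaussian
copula transform, and shows the two properties that make the estimator
attractive: it recovers the analytic value, and it is exactly invariant
under monotone distortions of the marginals.
"""

import numpy as np

from copulafc import gcmi, rescale_mi

rng = np.random.default_rng(0)
r = 0.5
cov = [[1.0, r], [r, 1.0]]
z = rng.multivariate_normal([0, 0], cov, size=10_000).T
x, y = z[:1], z[1:]

analytic = -0.5 * np.log2(1 - r**2)
estimate = gcmi(x, y)

print(f"analytic MI at r={r}:        {analytic:.4f} bits")
print(f"Gaussian-copula estimate:    {estimate.value:.4f} bits")
print(f"rescaled to |r| scale:       {rescale_mi(estimate):.4f}  (true |r| = {r})")

# Rank invariance: distorting the marginals changes nothing, bit for bit.
distorted = gcmi(np.exp(x), y**3)
print(f"after exp/cube distortions:  {distorted.value:.4f} bits "
      f"(identical: {distorted.value == estimate.value})")
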