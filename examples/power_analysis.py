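"""Prospective-study sample size for a paired signed-rank comparison of
two predictors' residual magnitudes.

The required n is found by Monte-Carlo simulation (binary search over n,
simulating the paired signed-rank test at each candidate). On a normal
shift it should sit close to the closed-form paired-t sample size
inflated by pi/3 (the inverse of the signed-rank test's asymptotic
relative efficiency 3/pi under normality).
"""

import numpy as np
from scipy import stats as sps

from popset.stats import required_sample_size

rng = np.random.default_rng(1)
# model residual magnitudes ~ N(5, 1); reference predictor is 0.6 worse
res_model = rng.normal(5.0, 1.0, 20000)
res_reference = rng.normal(5.6, 1.0, 20000)

n = required_sample_size(res_model, res_reference,
                         power=0.90, alpha=0.05, seed=1, n_reps=1500)
z = sps.norm.ppf(0.975) + sps.norm.ppf(0.90)
n_closed = (z * np.sqrt(2) / 0.6) ** 2 * np.pi / 3
print(f"Monte-Carlo required sample size: {n}")
print(f"closed-form paired-t x pi/3:      {n_closed:.1f}")
print(f"ratio: {n / n_closed:.3f}")
print("\nAt this n the paired signed-rank test detects the 0.6-point "
      "residual difference with 90% power at alpha = 0.05.")
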