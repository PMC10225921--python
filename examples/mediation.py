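"""Quasi-Bayesian mediation on a planted exposure → mediator → outcome chain.

Generates data where the exposure acts on the outcome only through the
mediator (a = b = 0.8, no direct path), then estimates the indirect effect
with its percentile CI and the three-part significance rule: indirect CI
excludes zero, total effect significant, direct effect not.
"""

import numpy as np

from dyadlink import StatsConfig, mediate

rng = np.random.default_rng(3)
n = 200
x = rng.normal(size=n)                  # exposure
m = 0.8 * x + rng.normal(size=n)        # mediator
y = 0.8 * m + rng.normal(size=n)        # outcome: no direct x path

res = mediate(x, m, y, StatsConfig(seed=3))
print(f"a (x->m):        {res.a:+.3f}")
print(f"b (m->y | x):    {res.b:+.3f}")
print(f"c (total):       {res.c:+.3f}  p={res.p_total:.2g}")
print(f"c' (direct):     {res.c_prime:+.3f}  p={res.p_direct:.2g}")
print(f"indirect a*b:    {res.indirect:+.3f}  "
      f"95% CI [{res.ci_low:+.3f}, {res.ci_high:+.3f}]  p={res.p_indirect:.3f}")
print(f"mediation significant: {res.significant}")
# expect indirect near 0.64 with the CI excluding zero and c' near zero
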