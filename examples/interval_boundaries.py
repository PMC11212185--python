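"""Interval-hypothesis boundaries for a three-level Poisson KRI.

When each risk level is an interval of rates rather than a point estimate,
the optimal integer decision cutoffs minimise the average decision error
rate (uniform within-interval rate, prior over levels) and must be found
numerically.  Capping the top interval only at the parameter's natural
maximum widens the high-risk boundary relative to the point-hypothesis
one.
"""

import rbmon as rb
from rbmon.intervals import IntervalHypothesisSpec

# Site-level event counts out of 20 subjects; levels at 55%, 40%, 25%.
n = 20
spec = IntervalHypothesisSpec(
    endpoints=[0.55 * n, 0.40 * n, 0.25 * n], upper_cap=float(n)
)
res = rb.optimize_interval_boundaries(spec)
print(f"interval cutoffs (counts of {n})   : {res.cutoffs}, "
      f"average error {res.error_rate:.3f}")

simple = rb.poisson_boundary(0.55 * n, 0.40 * n)
print(f"point-hypothesis top boundary      : {simple:.2f} "
      f"(interval cutoff {res.cutoffs[0]} is wider: the top interval "
      "stretches to 100%)")

post = rb.posterior_given_tau(9, spec)
print("posterior over levels at tau=9     : "
      + ", ".join(f"{p:.3f}" for p in post))
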