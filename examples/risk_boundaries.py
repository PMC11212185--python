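"""Optimal risk boundaries for single KRIs under each observation model.

Builds two-level risk specifications (high / low) and prints the decision
boundary that minimises the prior-weighted misclassification probability.
With equal priors the boundary always lies between the two level
estimates; an informative prior shifts it toward the level the sponsor
considers less likely.
"""

import rbmon as rb

# A once-only binary KRI: discontinuation proportions 30% (high) vs 10% (low).
pi = rb.binomial_boundary(0.30, 0.10)
print(f"binomial 30%/10%, equal priors      : {100 * pi:.2f}%  (midpoint would be 20%)")

# The same KRI when the sponsor believes low-risk sites outnumber high 7:3.
pi_inf = rb.binomial_boundary(0.30, 0.10, n_k=50, prior_hi=3, prior_lo=7)
print(f"binomial, 7:3 low:high prior, n=50  : {100 * pi_inf:.2f}%  (prior raises it)")

# Recurrent adverse events: 12 vs 9 expected events per subject over the
# snapshot exposure -> a boundary on the count scale.
theta = rb.poisson_boundary(12, 9)
print(f"poisson 12/9 events per subject     : {theta:.3f} events")

# Time-to-event KRI: hazard 2/mo (high) vs 1/mo (low); observed MEAN TIMES
# below the boundary indicate the riskier side.
e = rb.exponential_boundary(2.0, 1.0)
print(f"exponential hazards 2/1             : mean time {e:.4f} months "
      f"(= 1/poisson boundary {1 / rb.poisson_boundary(2.0, 1.0):.4f})")

# A continuous KRI (e.g. a safety lab): means 35 vs 25, any common variance.
delta = rb.normal_boundary(35.0, 25.0, sigma2=16.0)
print(f"normal means 35/25                  : {delta:.1f} (midpoint under equal priors)")
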