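"""Combining several KRIs into one site-level boundary.

Three once-only binary KRIs with different incidence levels cannot be
pooled as a single binomial, so each proportion is converted to a hazard
rate and the combined comparison happens on the Poisson-process count
scale.  Weights let the sponsor emphasise better-estimated KRIs; the
weight applies identically to the boundary and to the observed statistic.
"""

import rbmon as rb

# High/low incidence proportions over a 6-month reference follow-up.
levels = [(0.40, 0.10), (0.25, 0.04), (0.10, 0.01)]
specs = [
    rb.RiskLevelSpec(
        f"kri_{j + 1}", "poisson_process",
        tuple(rb.proportion_to_rate(p, 6.0) for p in lv),
    )
    for j, lv in enumerate(levels)
]

t_k = 2.0  # months of mean exposure at this monitoring snapshot
combined = rb.combine_weighted(specs, t_per_kri=t_k)
bset = rb.boundary_set(combined, t_k=t_k)
print(f"combined level products lambda_g*t : {[round(v, 4) for v in combined.values]}")
print(f"combined boundary (events/subject) : {bset.boundaries[0]:.4f}")

# Data-driven weights: KRIs with wider level gaps carry more weight.
w = rb.euclidean_weights(
    [rb.RiskLevelSpec(f"kri_{j + 1}", "binomial", lv, reference_time=6.0)
     for j, lv in enumerate(levels)]
)
print(f"euclidean-distance weights         : "
      f"{ {k: round(v, 3) for k, v in w.weights.items()} }")

weighted = rb.combine_weighted(specs, w, t_per_kri=t_k)
print(f"weighted boundary                  : "
      f"{rb.boundary_set(weighted, t_k=t_k).boundaries[0]:.4f}")

# An observed snapshot: 16 subjects, 5 events across the three KRIs.
e_hat = 5 / 16
level = rb.classify(e_hat, bset)
print(f"observed E_k = {e_hat:.3f}  ->  risk level {level} "
      f"({'on-site visit required' if level == 1 else 'no visit needed'})")
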