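# Methods

## Decision model

A site's observed KRI outcome is modelled per endpoint type: binomial for
once-only events (withdrawal, first occurrence of an AE), Poisson for
recurrent counts, exponential for event times, normal for continuous
measures. Risk levels are point hypotheses `H_g` on the parameter, ordered
so level 1 is riskiest, with prior masses `Pr(H_g)`. The decision error
rate of a cutoff is the prior-weighted sum of the misclassification
probabilities under each hypothesis, written with cumulative mass functions
evaluated at the floored cutoff; because that objective is piecewise
monotone between adjacent integer cutoffs, its minimiser has a closed form
(`rbmon.boundaries`). The test suite verifies, by exhaustive enumeration
over integer cutoffs with exact CDFs, that the floored closed-form boundary
attains the minimum error for randomized configurations of both the Poisson
and binomial families.

Conventions worth stating explicitly:

- **Units.** Time is months throughout; rates are events per
  subject-month. Proportions convert to rates through
  `λ = −ln(1−p)/t_ref` (exponential event-time assumption) and back via
  `p = 1−exp(−λ t)`.
- **Priors** are positive masses, not required to sum to 1; only adjacent
  ratios enter the formulas. `PriorSpec.normalized()` exists for
  reporting. Raising `Pr(H_{g+1})/Pr(H_g)` strictly raises the boundary —
  the lever used to relax a window known to be contaminated by an external
  shock.
- **Ties** at a boundary classify to the lower-risk side (the low-risk
  branch carries the `≤`).
- **Direction.** For KRIs where suspiciously *low* values are risky
  (AE under-reporting), levels are ordered by risk, the formulas receive
  value-ordered inputs with priors flipped alongside, and the comparison
  operator is inverted at classification time.
- **Degenerate inputs** (equal adjacent estimates, zero variance,
  `p = 1`) raise `DomainError` rather than returning infinities.

## Multi-KRI combination

Poisson and normal families are additive; binomial is additive only when
all KRIs share per-level proportions (then the pooled comparison uses
`n_k = Σ n_jk`). Heterogeneous binary KRIs are combined by converting each
proportion to a rate and summing `w_j λ_jg t_jk` on the Poisson-process
scale; the same weights multiply the observed per-KRI statistics so the
comparison stays valid. For once-only KRIs the count boundary converts to a
proportion boundary via `π* = 1−exp(−Θ)`; on a grid of two-level configs
with adjacent gaps ≤ 0.15 the gap `|π*−π|` stays below 0.01 (asserted in
the tests), so the two routes classify identically outside a ±0.01 band.
The Euclidean-distance weighting rule is implemented as: per-KRI mean
adjacent-level gap, normalised to sum to the number of KRIs — the exact
formula is not pinned down by the published description, so this reduction
(one KRI → weight 1, equal gaps → equal weights) is the package's choice.

## Interval hypotheses

When a level is an interval `λ_g ≤ Λ < λ_{g−1}` the objective becomes the
average decision error rate, integrating a uniform within-interval density
for the rate (the default, and the only density currently implemented).
Mixing `Poisson(Λ)` uniformly over `(a, b)` gives the marginal count pmf
`(F(τ; a) − F(τ; b))/(b − a)`, which makes posteriors and error rates exact
finite sums. No closed-form minimiser exists; `optimize_interval_boundaries`
scans all strictly ordered integer cutoff vectors (feasible because
supports are small in this application) and is verified against a naive
double-loop and a Monte-Carlo estimate. The top interval needs an explicit
cap because Poisson rates are unbounded; the natural choice caps at the
parameter's maximum (100% for a proportion-derived count scale), which
widens the top interval and pushes the high-risk boundary above its
point-hypothesis counterpart. Only the Poisson case is exact; other
families would need their own mixture CDFs and are out of scope.

## Assessment pipeline

`summarize_site` includes subjects enrolled strictly before the monitoring
time; exposure is `min(censor, T − enrollment)`. Empty sites and windows
are excluded with a logged notice, never errored, and never enter accuracy
denominators. Follow-up time is shared across KRIs at a site by default
(mean exposure), with per-KRI override. Binomial risk levels are
re-expressed at the snapshot exposure (rate round-trip) before the boundary
is computed. For exponential KRIs the boundary is compared against an
observed quantile survival time after multiplying by `−ln(Pr_jk)`; because
that printed multiplier conflicts with reading `Pr_jk` as the fraction who
already had the event (which would give `−ln(1−Pr_jk)`), both conventions
are implemented (`literal`, the default as printed, and
`survival_quantile`) and coincide at `Pr_jk = 0.5`.

Windows are fixed-duration, cut on calendar time (trial origin) or study
days (per-subject first dose). Each window is assessed independently with
levels re-adjusted to the window exposure; very short stub windows at the
end of follow-up therefore carry tiny denominators and noisy colors — a
display consideration, not a modelling one. Traffic lights: level 1 red,
level G green, anything between amber.

## Funnel comparator

"Conservative nominal" limits are exact binomial tail inversions
(Clopper-Pearson style), not normal approximations: the upper limit is the
smallest `x/n` with `P(X ≥ x) ≤ (1−conf)/2` under the overall proportion,
the lower limit the largest `x/n` with `P(X ≤ x) ≤ (1−conf)/2` (0 when no
`x` qualifies). Whether the original proposal used mid-p tails is not
documented; pure exact tails were chosen, which makes the realised flag
rate under the null at most the nominal level (verified by simulation).

## Simulation engine

The scenario generator emulates competitive multicenter recruitment:

- site sizes multinomial over fixed weights (5 sites: .25/.25/.2/.2/.1;
  10 sites: .15×3/.1×4/.05×3); sites drawn empty are excluded;
- true risk levels allocated deterministically by the high:low ratio
  (remainder to low risk) and randomly permuted across sites each
  replication;
- enrollment `a·U(0,1)` over the accrual window (single-site scenarios:
  simultaneous enrollment, 10-month horizon);
- once-only events as exponential times with rates from the level
  proportions over the reference follow-up `t_ref = f − a/2` (multicenter)
  or 10 months (single site);
- recurrent-count scenarios draw per-subject Poisson counts at the level
  means over unit exposure, with the exposure configurable
  (`poisson_exposure`);
- classification per site against the combined Poisson-process boundary at
  the site's mean observed exposure; accuracy pooled over sites ×
  replications (1000 replications by default).

**Monitoring-time convention.** "x% of monitoring data collected" is
mapped to the calendar time `T_m = m·(a/2 + f)` — m of the mean
per-subject study span — for multicenter scenarios and `T_m = 10·m` months
for single-site ones. The fraction is not defined operationally in the
source description; of the candidate readings implemented
(`mean_span_fraction`, `trial_fraction` = `m·(a+f)`,
`accrual_plus_followup_fraction` = `a+m·f`, `followup_fraction` = `m·f`),
the mean-span reading reproduces the published scenario accuracy table most
closely and is the package default; the others remain selectable per
scenario.

What the generator does *not* emulate: site-level covariates, dependence
between KRIs (competing risks), time-varying hazards within a window,
informative censoring, or operational artefacts (data-entry lags, partial
CRFs). Passing operating-characteristic tests therefore demonstrates the
boundary mathematics and the monitoring logic under idealised sampling,
not performance on any specific real trial.

Problem sizes used in the shipped tests and acceptance script — 1000
replications per scenario, trials up to 10 sites × 400 subjects × 3 KRIs —
were chosen to keep Monte-Carlo standard errors near 0.4 percentage points
while the full suite stays fast.

## Known limitations

- Gamma (summed exponential) and Weibull boundaries are not implemented.
- Interval-hypothesis boundaries are exact for Poisson only.
- The binomial combination requires equal per-level proportions; the rate
  route is an approximation whose error grows with the level gap (bounded
  on the tested grid, not in general).
- The synthetic example-like fixture stands in for real trial extracts and
  is labelled synthetic; no connector to EDC/CDISC data exists.
- Multiplicity across sites is deliberately not adjusted: the Bayesian
  decision framing grades each site against its own posterior error, so no
  family-wise correction is applied.
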