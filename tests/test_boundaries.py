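"""Unit and property tests for the closed-form risk boundaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rbmon as rb
from rbmon.boundaries import ConfigurationError, DomainError

E = math.e


# ---------------------------------------------------------------------------
# Independent oracles: exhaustive integer-cutoff error minimisation
# ---------------------------------------------------------------------------


def poisson_cutoff_oracle(lam_hi, lam_lo, w_hi, w_lo, cmax=None):
    """Integer cutoff minimising the prior-weighted decision error
    w_hi * P(X_hi <= c) + w_lo * P(X_lo > c), by full scan."""
    if cmax is None:
        cmax = int(math.ceil(lam_hi + 10 * math.sqrt(lam_hi))) + 2
    cs = np.arange(-1, cmax + 1)
    err = w_hi * stats.poisson.cdf(cs, lam_hi) + w_lo * stats.poisson.sf(cs, lam_lo)
    return cs, err


def binomial_cutoff_oracle(p_hi, p_lo, n, w_hi, w_lo):
    cs = np.arange(-1, n + 1)
    err = w_hi * stats.binom.cdf(cs, n, p_hi) + w_lo * stats.binom.sf(cs, n, p_lo)
    return cs, err


# ---------------------------------------------------------------------------
# Poisson
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "hi, lo, m_hi, m_lo, expected",
    [
        (E, 1.0, 1.0, 1.0, E - 1),
        (E, 1.0, 1.0, E, E),
        (12.0, 9.0, 1.0, 1.0, 3.0 / math.log(4.0 / 3.0)),
    ],
)
def test_poisson_boundary_values(hi, lo, m_hi, m_lo, expected):
    assert rb.poisson_boundary(hi, lo, m_hi, m_lo) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("hi, lo", [(1.0, 1.0), (2.0, 3.0), (-1.0, -2.0), (1.0, 0.0)])
def test_poisson_boundary_rejects_bad_ordering(hi, lo):
    with pytest.raises(DomainError):
        rb.poisson_boundary(hi, lo)


def test_poisson_floor_matches_exhaustive_error_minimisation(rng):
    """The integer decision cutoff implied by the closed form equals the
    argmin of the exact prior-weighted error, for random configurations."""
    for _ in range(60):
        lam_lo = rng.uniform(0.5, 10.0)
        lam_hi = lam_lo * rng.uniform(1.2, 3.0)
        w_hi, w_lo = rng.uniform(0.2, 2.0, 2)
        theta = rb.poisson_boundary(lam_hi, lam_lo, w_hi, w_lo)
        cs, err = poisson_cutoff_oracle(lam_hi, lam_lo, w_hi, w_lo)
        c_star = math.floor(theta)
        assert err[cs == c_star][0] <= err.min() + 1e-12


# ---------------------------------------------------------------------------
# Poisson process
# ---------------------------------------------------------------------------


def test_poisson_process_boundary_scenario_values():
    bset = rb.poisson_process_boundary([12 * 0.33, 9 * 0.33])
    assert bset.boundaries[0] == pytest.approx(0.99 / math.log(4 / 3), rel=1e-12)
    # same integer-cutoff oracle with means 3.96 / 2.97
    cs, err = poisson_cutoff_oracle(3.96, 2.97, 0.5, 0.5)
    c_star = math.floor(bset.boundaries[0])
    assert err[cs == c_star][0] <= err.min() + 1e-12


def test_poisson_process_equal_products_rejected():
    with pytest.raises(DomainError):
        rb.poisson_process_boundary([2 * E, 2 * E])


def test_prior_ratio_monotonicity():
    """Raising Pr(H_{g+1}) relative to Pr(H_g) strictly raises the boundary
    on count, proportion and mean scales."""
    ratios = [0.5, 1.0, 2.0, 4.0]
    pois = [rb.poisson_boundary(4, 2, 1.0, r) for r in ratios]
    bino = [rb.binomial_boundary(0.4, 0.2, 10, 1.0, r) for r in ratios]
    norm = [rb.normal_boundary(3.0, 1.0, 2.0, 1.0, r) for r in ratios]
    for seq in (pois, bino, norm):
        assert all(a < b for a, b in zip(seq, seq[1:]))


def test_first_term_invariant_to_exposure():
    """The prior term of the Poisson-process boundary does not depend on
    t_k: exposure cancels inside the log ratio."""
    lam = (0.3, 0.1)
    for t in (0.5, 2.0, 7.3):
        with_prior = rb.poisson_boundary(lam[0] * t, lam[1] * t, 1.0, 2.5)
        equal = rb.poisson_boundary(lam[0] * t, lam[1] * t)
        assert with_prior - equal == pytest.approx(
            math.log(2.5) / math.log(3.0), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Binomial
# ---------------------------------------------------------------------------


def test_binomial_boundary_published_value():
    assert rb.binomial_boundary(0.30, 0.10) == pytest.approx(0.1862, abs=5e-5)
    # independent of n under equal priors
    assert rb.binomial_boundary(0.30, 0.10, n_k=500) == rb.binomial_boundary(0.30, 0.10)


def test_binomial_boundary_is_half_iff_estimates_sum_to_one(rng):
    assert rb.binomial_boundary(0.70, 0.30) == pytest.approx(0.5, rel=1e-12)
    for _ in range(20):
        p_lo = rng.uniform(0.05, 0.45)
        p_hi = rng.uniform(p_lo + 0.05, 0.95)
        b = rb.binomial_boundary(p_hi, p_lo)
        if abs(p_hi + p_lo - 1) > 1e-9:
            assert abs(b - 0.5) > 1e-12
        assert rb.binomial_boundary(1 - p_lo, p_lo) == pytest.approx(0.5, rel=1e-12)


def test_binomial_floor_matches_exhaustive_error_minimisation():
    n = 20
    pi = rb.binomial_boundary(0.55, 0.40, n_k=n, prior_hi=3.0, prior_lo=7.0)
    cs, err = binomial_cutoff_oracle(0.55, 0.40, n, 3.0, 7.0)
    c_star = math.floor(n * pi + 1e-12)
    assert err[cs == c_star][0] <= err.min() + 1e-12


@given(
    p_lo=st.floats(0.02, 0.5),
    gap=st.floats(0.02, 0.4),
    n=st.integers(5, 60),
    ratio=st.floats(0.25, 4.0),
)
@settings(max_examples=80, derandomize=True)
def test_binomial_oracle_equivalence_property(p_lo, gap, n, ratio):
    p_hi = min(p_lo + gap, 0.98)
    pi = rb.binomial_boundary(p_hi, p_lo, n_k=n, prior_hi=1.0, prior_lo=ratio)
    cs, err = binomial_cutoff_oracle(p_hi, p_lo, n, 1.0, ratio)
    c_star = min(max(math.floor(n * pi + 1e-9), -1), n)
    assert err[cs == c_star][0] <= err.min() + 1e-9


@pytest.mark.parametrize("p_hi, p_lo", [(0.3, 0.3), (0.1, 0.3), (1.0, 0.5), (0.5, 0.0)])
def test_binomial_boundary_rejects_bad_proportions(p_hi, p_lo):
    with pytest.raises(DomainError):
        rb.binomial_boundary(p_hi, p_lo)


# ---------------------------------------------------------------------------
# Exponential and normal
# ---------------------------------------------------------------------------


def test_exponential_boundary_value_and_reciprocity(rng):
    assert rb.exponential_boundary(2.0, 1.0) == pytest.approx(math.log(2), rel=1e-12)
    for _ in range(20):
        lo = rng.uniform(0.1, 5.0)
        hi = lo * rng.uniform(1.1, 4.0)
        assert rb.exponential_boundary(hi, lo) == pytest.approx(
            1.0 / rb.poisson_boundary(hi, lo), rel=1e-12
        )
    with pytest.raises(DomainError):
        rb.exponential_boundary(2.0, 2.0)


def test_normal_boundary_midpoint_under_equal_priors(rng):
    assert rb.normal_boundary(35.0, 25.0, 4.0) == pytest.approx(30.0)
    for _ in range(20):
        mu_lo = rng.uniform(-10, 10)
        mu_hi = mu_lo + rng.uniform(0.5, 10)
        s2 = rng.uniform(0.1, 50)
        assert rb.normal_boundary(mu_hi, mu_lo, s2) == pytest.approx(
            (mu_hi + mu_lo) / 2, rel=1e-12
        )
    assert rb.normal_boundary(1.0, -1.0, 2.0, 1.0, E) == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(DomainError):
        rb.normal_boundary(1.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# Conversions and time adjustment
# ---------------------------------------------------------------------------


def test_rate_proportion_conversions():
    assert rb.proportion_to_rate(0.0, 5.0) == 0.0
    assert rb.proportion_to_rate(0.3, 10.0) == pytest.approx(0.0356675, abs=1e-7)
    assert rb.rate_to_proportion(0.0356675, 10.0) == pytest.approx(0.3, abs=1e-6)
    assert rb.rate_to_proportion(0.0, 3.0) == 0.0
    with pytest.raises(DomainError):
        rb.proportion_to_rate(1.0, 2.0)
    with pytest.raises(DomainError):
        rb.rate_to_proportion(-0.1, 2.0)


@given(p=st.floats(0.0, 0.999), t=st.floats(0.1, 100.0))
@settings(max_examples=60, derandomize=True)
def test_conversion_roundtrip(p, t):
    assert rb.rate_to_proportion(rb.proportion_to_rate(p, t), t) == pytest.approx(
        p, abs=1e-12
    )


def test_adjust_levels_for_time():
    spec = rb.RiskLevelSpec("w", "binomial", (0.5, 0.2), reference_time=24.0)
    same = rb.adjust_levels_for_time(spec, 24.0)
    assert same.levels == pytest.approx(spec.levels)
    short = rb.adjust_levels_for_time(spec, 2.0)
    assert short.levels[0] == pytest.approx(1 - 0.5 ** (2 / 24), abs=1e-6)
    longer = rb.adjust_levels_for_time(spec, 36.0)
    assert all(a < b for a, b in zip(short.levels, longer.levels))
    with pytest.raises(ConfigurationError):
        rb.adjust_levels_for_time(
            rb.RiskLevelSpec("w", "binomial", (0.5, 0.2)), 2.0
        )


def test_theta_to_pi():
    assert rb.theta_to_pi(0.0) == 0.0
    assert rb.theta_to_pi(-math.log(0.8)) == pytest.approx(0.2, rel=1e-12)
    with pytest.raises(DomainError):
        rb.theta_to_pi(-0.1)


def test_count_vs_proportion_boundary_agreement_on_grid():
    """For once-only KRIs with non-informative priors the count boundary
    converted by 1-exp(-theta) agrees with the direct proportion boundary
    to within 0.01 wherever adjacent levels are at most 0.15 apart."""
    worst = 0.0
    for p_lo in np.arange(0.02, 0.80, 0.02):
        for gap in np.arange(0.02, 0.1501, 0.01):
            p_hi = p_lo + gap
            if p_hi >= 0.95:
                continue
            lam = [-math.log(1 - p) for p in (p_hi, p_lo)]
            theta = rb.poisson_boundary(lam[0], lam[1])
            pi_star = rb.theta_to_pi(theta)
            pi = rb.binomial_boundary(p_hi, p_lo)
            worst = max(worst, abs(pi_star - pi))
    assert worst < 0.01


# ---------------------------------------------------------------------------
# Combination, weights, boundary sets
# ---------------------------------------------------------------------------


def _scen1_specs():
    return [
        rb.RiskLevelSpec(f"kri_{i}", "poisson_process", lv)
        for i, lv in enumerate(
            [(-math.log(0.60), -math.log(0.90)),
             (-math.log(0.75), -math.log(0.96)),
             (-math.log(0.90), -math.log(0.99))]
        )
    ]


def test_combine_weighted_plain_sum_and_zero_weight():
    specs = _scen1_specs()
    combined = rb.combine_weighted(specs, t_per_kri=1.0)
    assert combined.values[0] == pytest.approx(0.9039, abs=2e-4)
    w0 = rb.KRIWeights({"kri_0": 0.0, "kri_1": 1.0, "kri_2": 1.0})
    dropped = rb.combine_weighted(specs, w0, t_per_kri=1.0)
    assert dropped.values[0] == pytest.approx(
        combined.values[0] + math.log(0.60), abs=1e-12
    )


def test_combine_rejects_mixed_families_and_unequal_binomials():
    a = rb.RiskLevelSpec("a", "poisson_process", (0.4, 0.1))
    b = rb.RiskLevelSpec("b", "binomial", (0.4, 0.1), reference_time=6.0)
    with pytest.raises(ConfigurationError):
        rb.combine_weighted([a, b])
    c = rb.RiskLevelSpec("c", "binomial", (0.3, 0.1), reference_time=6.0)
    with pytest.raises(ConfigurationError):
        rb.combine_weighted([b, c])


def test_euclidean_weights():
    one = rb.RiskLevelSpec("only", "binomial", (0.4, 0.1), reference_time=6.0)
    assert rb.euclidean_weights([one]).weights["only"] == pytest.approx(1.0)
    a = rb.RiskLevelSpec("a", "binomial", (0.30, 0.20), reference_time=6.0)
    b = rb.RiskLevelSpec("b", "binomial", (0.45, 0.15), reference_time=6.0)
    w = rb.euclidean_weights([a, b]).weights
    assert w["a"] == pytest.approx(0.5)
    assert w["b"] == pytest.approx(1.5)
    c = rb.RiskLevelSpec("c", "binomial", (0.40, 0.30), reference_time=6.0)
    equal = rb.euclidean_weights([a, c]).weights
    assert equal["a"] == pytest.approx(equal["c"]) == pytest.approx(1.0)


def test_boundary_set_containment_and_ordering(rng):
    """Under equal priors every boundary lies strictly between its adjacent
    level estimates, and boundaries are strictly ordered."""
    for _ in range(25):
        p = np.sort(rng.uniform(0.02, 0.95, 3))[::-1]
        if min(np.diff(p[::-1])) < 0.02:
            continue
        spec = rb.RiskLevelSpec("x", "binomial", tuple(p), reference_time=6.0)
        bset = rb.boundary_set(spec)
        for g, b in enumerate(bset.boundaries):
            assert p[g + 1] < b < p[g]
        assert bset.boundaries[0] > bset.boundaries[1]


def test_lower_is_riskier_direction():
    """Under-reporting KRIs: smaller observed proportions are riskier and
    the comparison operator is inverted at classification time."""
    spec = rb.RiskLevelSpec(
        "ae", "binomial", (0.072, 0.122), reference_time=12.0,
        direction="lower_is_riskier",
    )
    bset = rb.boundary_set(spec)
    (b,) = bset.boundaries
    assert 0.072 < b < 0.122
    assert b == pytest.approx(rb.binomial_boundary(0.122, 0.072), rel=1e-12)
    assert rb.classify(0.05, bset) == 1
    assert rb.classify(0.20, bset) == 2


def test_levels_from_overall_offset_rules():
    assert rb.levels_from_overall(0.25, [0.30, 0.15]) == pytest.approx((0.55, 0.40))
    low = rb.levels_from_overall(0.222, [0.15, 0.10], "lower_is_riskier")
    assert low == pytest.approx((0.072, 0.122))


def test_prior_spec_validation():
    with pytest.raises(ConfigurationError):
        rb.PriorSpec([1.0, 0.0])
    with pytest.raises(ConfigurationError):
        rb.PriorSpec([1.0])
    assert rb.PriorSpec.noninformative(3).normalized() == pytest.approx((1 / 3,) * 3)


def test_risk_level_spec_rejects_non_monotone():
    with pytest.raises(DomainError):
        rb.RiskLevelSpec("x", "binomial", (0.2, 0.2), reference_time=6.0)
    with pytest.raises(DomainError):
        rb.RiskLevelSpec("x", "poisson", (1.0, 2.0))
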