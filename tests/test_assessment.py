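"""Tests for snapshots, classification, voting and windowed assessment."""

import math

import numpy as np
import pandas as pd
import pytest

import rbmon as rb
from rbmon.assessment import (
    combine_snapshots,
    level_color,
    records_to_frame,
    summarize_site,
)
from rbmon.boundaries import ConfigurationError, DomainError, PriorSpec


def _subjects(site="s1", kri="k1", n=10, events=(), enroll=0.0, censor=12.0):
    recs = []
    for i in range(n):
        ev = (events[i],) if i < len(events) and events[i] is not None else ()
        recs.append(
            rb.SubjectRecord(site, kri, enrollment_time=enroll,
                             censor_time=censor, event_times=ev)
        )
    return recs


def test_summarize_counts_once_only_events():
    recs = _subjects(n=10, events=(1.0, 2.0, 3.0))
    snap = summarize_site(recs, monitoring_time=12.0, family="binomial")
    assert snap.n == 10
    assert snap.e_hat == pytest.approx(0.3)
    assert snap.event_fraction == pytest.approx(0.3)
    assert snap.t_jk == pytest.approx(12.0)


def test_late_enrollment_contributes_nothing():
    recs = _subjects(n=5, events=(1.0,)) + _subjects(n=3, enroll=20.0, events=(1.0,))
    snap = summarize_site(recs, monitoring_time=10.0, family="binomial")
    assert snap.n == 5
    # exposure capped by monitoring time, not the censor time
    assert snap.t_jk == pytest.approx(10.0)


def test_empty_site_flagged_not_raised():
    recs = _subjects(n=3, enroll=20.0)
    snap = summarize_site(recs, monitoring_time=10.0, family="binomial")
    assert snap.empty and snap.n == 0


def test_weighted_multi_kri_statistic_matches_hand_computation():
    snaps = [
        summarize_site(_subjects(kri=k, n=10, events=evs), 12.0, "binomial")
        for k, evs in [("a", (1.0, 2.0)), ("b", (3.0,)), ("c", (1.0, 2.0, 3.0))]
    ]
    w = rb.KRIWeights({"a": 1.0, "b": 2.0, "c": 0.5})
    assert combine_snapshots(snaps, w) == pytest.approx(
        1.0 * 0.2 + 2.0 * 0.1 + 0.5 * 0.3
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _bset(bounds=(0.3, 0.1)):
    return rb.BoundarySet(
        family="poisson_process", scale="count_per_subject_over_t",
        boundaries=bounds, prior_used=PriorSpec.noninformative(len(bounds) + 1),
    )


@pytest.mark.parametrize(
    "stat, level", [(0.05, 3), (0.2, 2), (0.35, 1), (0.1, 3), (0.3, 2)]
)
def test_classify_three_levels_with_tie_to_lower_risk(stat, level):
    assert rb.classify(stat, _bset()) == level


def test_classify_rejects_non_finite():
    with pytest.raises(DomainError):
        rb.classify(float("nan"), _bset())


def test_classify_mean_time_scale_reversed():
    bset = rb.BoundarySet(
        family="exponential", scale="mean_time", boundaries=(0.5, 2.0),
        prior_used=PriorSpec.noninformative(3),
    )
    assert rb.classify(0.3, bset) == 1  # short times = high risk
    assert rb.classify(1.0, bset) == 2
    assert rb.classify(3.0, bset) == 3


def test_per_kri_vote():
    highs = [1] * 5 + [3] * 5
    assert rb.per_kri_vote(highs, at_or_above=1, count=5)
    assert not rb.per_kri_vote([1] * 4 + [3] * 6, at_or_above=1, count=5)
    assert rb.per_kri_vote([3, 3, 1], at_or_above=1, count=1)
    with pytest.raises(ConfigurationError):
        rb.per_kri_vote([1, 2], at_or_above=1, count=3)


def test_exponential_time_threshold():
    e = 0.6931
    assert rb.exponential_time_threshold(e, math.exp(-1)) == pytest.approx(e)
    assert rb.exponential_time_threshold(e, 0.25) == pytest.approx(0.9609, abs=2e-4)
    lit = rb.exponential_time_threshold(e, 0.5, "literal")
    surv = rb.exponential_time_threshold(e, 0.5, "survival_quantile")
    assert lit == pytest.approx(surv)
    with pytest.raises(DomainError):
        rb.exponential_time_threshold(e, 1.0)


# ---------------------------------------------------------------------------
# Site assessment pipeline
# ---------------------------------------------------------------------------


@pytest.fixture
def binary_spec():
    return [rb.RiskLevelSpec("k1", "binomial", (0.30, 0.10), reference_time=12.0)]


def test_assess_trial_order_and_split_invariance(binary_spec, rng):
    recs = records_to_frame(
        _subjects(site="a", n=20, events=tuple(rng.uniform(0, 12, 8)))
        + _subjects(site="b", n=20, events=(1.0,))
    )
    base = rb.assess_trial(recs, binary_spec, 12.0)
    shuffled = rb.assess_trial(
        recs.sample(frac=1.0, random_state=1).reset_index(drop=True),
        binary_spec, 12.0,
    )
    assert [(a.site_id, a.level) for a in base] == [
        (a.site_id, a.level) for a in shuffled
    ]


def test_assess_skips_empty_sites(binary_spec):
    recs = records_to_frame(
        _subjects(site="a", n=5, events=(1.0,))
        + _subjects(site="late", n=4, enroll=30.0)
    )
    out = rb.assess_trial(recs, binary_spec, 12.0)
    assert [a.site_id for a in out] == ["a"]


def test_binomial_vs_rate_route_agreement(binary_spec):
    """Classification through the proportion boundary and through the
    rate-conversion count boundary agree outside a narrow band around the
    boundary (the conversion changes the cutoff by under 0.01)."""
    spec = binary_spec[0]
    pi = rb.binomial_boundary(0.30, 0.10)
    lam = [rb.proportion_to_rate(p, 12.0) for p in spec.levels]
    theta = rb.poisson_boundary(lam[0] * 12.0, lam[1] * 12.0)
    pi_star = rb.theta_to_pi(theta)
    bset_prop = rb.boundary_set(spec)
    for stat in np.arange(0.0, 0.6, 0.01):
        if abs(stat - pi) < 0.01:
            continue
        via_prop = rb.classify(stat, bset_prop)
        via_rate = 1 if -math.log1p(-min(stat, 0.999)) > theta else 2
        assert via_prop == via_rate, stat
    assert abs(pi_star - pi) < 0.01


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def _burst_records():
    """One site, 30 subjects followed 6 months; discontinuations cluster
    in the second 60-day window."""
    events = [None] * 30
    for i in range(4):
        events[i] = 2.5  # months; inside window 2 (2.0 - 4.0 mo at 60 d)
    return records_to_frame(_subjects(n=30, events=tuple(events), censor=6.0))


@pytest.fixture
def window_spec():
    return [rb.RiskLevelSpec("k1", "binomial", (0.20, 0.02), reference_time=2.0)]


def test_single_window_equals_whole_data(binary_spec):
    recs = records_to_frame(_subjects(n=20, events=(1.0, 2.0, 3.0, 4.0), censor=12.0))
    whole = rb.assess_trial(recs, binary_spec, 12.0)[0]
    wspec = rb.WindowSpec("study_day", duration_days=12.5 * 30.4375)
    windowed = rb.window_assess(recs, wspec, binary_spec)
    assert len(windowed) == 1
    assert windowed[0].level == whole.level
    assert windowed[0].statistic == pytest.approx(whole.statistic)


def test_event_burst_lights_only_its_window(window_spec):
    wspec = rb.WindowSpec("study_day", duration_days=60.0)
    out = rb.window_assess(_burst_records(), wspec, window_spec)
    colors = {a.window: a.color for a in out}
    burst = [w for w in colors if w[0] <= 2.5 < w[1]][0]
    assert colors[burst] == "red"
    assert all(c == "green" for w, c in colors.items() if w != burst)


def test_window_prior_flips_borderline_call(window_spec):
    """Down-weighting the high-risk hypothesis in one window raises its
    boundary and relaxes a borderline red call on the same data."""
    wspec = rb.WindowSpec("study_day", duration_days=60.0)
    base = rb.window_assess(_burst_records(), wspec, window_spec)
    prior = PriorSpec([1.0, 100.0])  # strong belief in the low-risk level
    eased = rb.window_assess(
        _burst_records(), wspec, window_spec,
        priors_per_window={1: prior},
    )
    base_lv = {a.window: a.level for a in base}
    eased_lv = {a.window: a.level for a in eased}
    burst = [w for w in base_lv if w[0] <= 2.5 < w[1]][0]
    assert base_lv[burst] == 1
    assert eased_lv[burst] > base_lv[burst]
    for w in base_lv:
        if w != burst:
            assert eased_lv[w] == base_lv[w]


def test_level_color_map():
    assert level_color(1, 3) == "red"
    assert level_color(2, 3) == "amber"
    assert level_color(3, 3) == "green"
    assert level_color(2, 2) == "green"
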