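"""Monte-Carlo operating characteristics of the optimal risk boundaries.

The scenario engine emulates multicenter trial monitoring: subjects accrue
uniformly over an accrual window, once-only KRI events arrive as
exponential times (rates converted from the per-level incidence
proportions), a monitoring snapshot is taken when a configurable fraction
of the trial has elapsed, and every site is classified against the
combined Poisson-process boundary.  The evaluation metric is the accuracy
of the site-level risk calls, pooled over sites and replications.

Recurrent-event scenarios draw per-subject Poisson counts directly.
Helper routines provide the exact (no-simulation) accuracy of any binomial
cutoff and boundary sweeps over candidate cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from . import boundaries as bnd
from .boundaries import ConfigurationError, DomainError, PriorSpec

MonitoringRule = Literal["mean_span_fraction", "trial_fraction",
                         "accrual_plus_followup_fraction", "followup_fraction"]

#: Site-size multinomial weights used throughout the scenario grid.
SITE_WEIGHTS_5 = (0.25, 0.25, 0.2, 0.2, 0.1)
SITE_WEIGHTS_10 = (0.15, 0.15, 0.15, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``kri_levels[j][g]`` is KRI ``j``'s level-``g`` estimate (incidence
    proportion for the binary family, events per subject for the Poisson
    family), highest risk first.  ``allocation`` is the high:...:low site
    ratio, applied deterministically to site counts (remainder to the
    lowest-risk group) and randomly permuted across sites each replication.
    """

    name: str
    total_n: int
    kri_levels: tuple[tuple[float, ...], ...]
    family: Literal["binary", "poisson"] = "binary"
    n_sites: int = 1
    site_size_probs: tuple[float, ...] | None = None
    allocation: tuple[int, ...] = (1, 1)
    accrual: float = 0.0
    followup: float = 0.0
    monitoring_fraction: float = 1.0
    horizon: float = 10.0  # single-site reference/monitoring horizon, months
    weights: tuple[float, ...] | None = None
    priors: PriorSpec | None = None
    monitoring_rule: MonitoringRule = "mean_span_fraction"
    poisson_exposure: float = 1.0

    def __post_init__(self):
        if self.total_n < 1:
            raise ConfigurationError("total_n must be >= 1")
        if not (0 < self.monitoring_fraction <= 1):
            raise ConfigurationError("monitoring_fraction must lie in (0, 1]")
        G = len(self.kri_levels[0])
        if any(len(lv) != G for lv in self.kri_levels):
            raise ConfigurationError("all KRIs need the same number of levels")
        if len(self.allocation) != G:
            raise ConfigurationError("allocation must give one cell per level")
        if self.n_sites > 1:
            if self.site_size_probs is None or len(self.site_size_probs) != self.n_sites:
                raise ConfigurationError("site_size_probs must match n_sites")
            if abs(sum(self.site_size_probs) - 1) > 1e-9:
                raise ConfigurationError("site_size_probs must sum to 1")
            if sum(self.allocation) > self.n_sites:
                raise ConfigurationError("allocation ratio cells exceed site count")

    @property
    def n_levels(self) -> int:
        return len(self.kri_levels[0])

    @property
    def reference_time(self) -> float:
        """Follow-up time over which the proportion estimates hold:
        the full horizon for a single site (simultaneous enrollment),
        ``f - a/2`` for multicenter competitive accrual."""
        if self.n_sites == 1:
            return self.horizon
        return self.followup - self.accrual / 2.0

    @property
    def monitoring_time(self) -> float:
        m = self.monitoring_fraction
        if self.n_sites == 1:
            return m * self.horizon
        if self.monitoring_rule == "mean_span_fraction":
            # m of the mean per-subject study span (a/2 enrollment wait + f)
            return m * (self.accrual / 2.0 + self.followup)
        if self.monitoring_rule == "trial_fraction":
            return m * (self.accrual + self.followup)
        if self.monitoring_rule == "accrual_plus_followup_fraction":
            return self.accrual + m * self.followup
        return m * self.followup

    def event_rates(self) -> np.ndarray:
        """Per-KRI, per-level hazard rates (per subject-month) implied by
        the binary level proportions at the reference time."""
        tref = self.reference_time
        if tref <= 0:
            raise ConfigurationError("reference time must be positive")
        return np.array(
            [[bnd.proportion_to_rate(p, tref) for p in lv] for lv in self.kri_levels]
        )

    def site_level_counts(self) -> np.ndarray:
        """Deterministic number of sites per level from the allocation."""
        total = sum(self.allocation)
        counts = [math.floor(self.n_sites * a / total) for a in self.allocation]
        counts[-1] += self.n_sites - sum(counts)
        return np.array(counts)


@dataclass
class SimResult:
    """Pooled operating characteristics of one scenario."""

    accuracy: float
    n_calls: int
    seed: int
    reps: int
    mc_se: float
    boundary_example: tuple[float, ...] = ()
    confusion: np.ndarray | None = None


def _truth_for_sites(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.n_sites == 1:
        probs = np.asarray(cfg.allocation, float)
        probs = probs / probs.sum()
        return np.array([rng.choice(cfg.n_levels, p=probs)])
    counts = cfg.site_level_counts()
    levels = np.repeat(np.arange(cfg.n_levels), counts)
    return rng.permutation(levels)


def _boundary_cutoffs(cfg: ScenarioConfig, products: np.ndarray) -> np.ndarray:
    """Adjacent-pair boundaries for combined level products (decreasing)."""
    priors = cfg.priors or PriorSpec.noninformative(cfg.n_levels)
    return np.array(
        [
            bnd.poisson_boundary(products[g], products[g + 1],
                                 priors.masses[g], priors.masses[g + 1])
            for g in range(cfg.n_levels - 1)
        ]
    )


def _classify(stat: float, cuts: np.ndarray) -> int:
    """0-based level; ties go to the lower-risk side."""
    for g, c in enumerate(cuts):
        if stat > c:
            return g
    return len(cuts)


def _rep_binary(cfg: ScenarioConfig, rates: np.ndarray, weights: np.ndarray,
                rng: np.random.Generator):
    T = cfg.monitoring_time
    truth = _truth_for_sites(cfg, rng)
    if cfg.n_sites == 1:
        sizes = np.array([cfg.total_n])
    else:
        sizes = rng.multinomial(cfg.total_n, cfg.site_size_probs)
    true_out, call_out = [], []
    for s in range(cfg.n_sites):
        n_s = int(sizes[s])
        if n_s == 0:
            continue
        if cfg.accrual > 0:
            enroll = rng.uniform(0.0, cfg.accrual, n_s)
        else:
            enroll = np.zeros(n_s)
        enrolled = enroll < T
        n_e = int(enrolled.sum())
        if n_e == 0:
            continue
        exposure = T - enroll[enrolled]
        if cfg.followup > 0:
            exposure = np.minimum(exposure, cfg.followup)
        lam = rates[:, truth[s]]  # (J,)
        # once-only events: exponential arrival within the exposure window
        ev_times = rng.exponential(1.0, size=(lam.size, n_e)) / lam[:, None]
        events = (ev_times <= exposure[None, :]).sum(axis=1)  # per KRI
        e_hat = float((weights * events).sum() / n_e)
        t_k = float(exposure.mean())
        products = (weights[:, None] * rates).sum(axis=0) * t_k
        cuts = _boundary_cutoffs(cfg, products)
        true_out.append(truth[s])
        call_out.append(_classify(e_hat, cuts))
    return true_out, call_out


def _rep_poisson(cfg: ScenarioConfig, weights: np.ndarray, rng: np.random.Generator):
    lam = np.asarray(cfg.kri_levels, float)  # (J, G) events per subject
    truth = _truth_for_sites(cfg, rng)
    if cfg.n_sites == 1:
        sizes = np.array([cfg.total_n])
    else:
        sizes = rng.multinomial(cfg.total_n, cfg.site_size_probs)
    t = cfg.poisson_exposure
    products = (weights[:, None] * lam).sum(axis=0) * t
    cuts = _boundary_cutoffs(cfg, products)
    true_out, call_out = [], []
    for s in range(cfg.n_sites):
        n_s = int(sizes[s])
        if n_s == 0:
            continue
        counts = rng.poisson(lam[:, truth[s]][:, None] * t, size=(lam.shape[0], n_s))
        e_hat = float((weights[:, None] * counts).sum() / n_s)
        true_out.append(truth[s])
        call_out.append(_classify(e_hat, cuts))
    return true_out, call_out


def run_scenario(cfg: ScenarioConfig, reps: int = 1000, seed: int = 0) -> SimResult:
    """Replicate a scenario and pool site-level classification accuracy.

    Sites drawn with zero subjects (or none enrolled by the monitoring
    time) are excluded from the denominator.  Deterministic given
    ``cfg`` and ``seed``.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    weights = (
        np.asarray(cfg.weights, float)
        if cfg.weights is not None
        else np.ones(len(cfg.kri_levels))
    )
    rates = cfg.event_rates() if cfg.family == "binary" else None
    G = cfg.n_levels
    confusion = np.zeros((G, G), dtype=int)
    for _ in range(reps):
        if cfg.family == "binary":
            tr, cl = _rep_binary(cfg, rates, weights, rng)
        else:
            tr, cl = _rep_poisson(cfg, weights, rng)
        for t_lv, c_lv in zip(tr, cl):
            confusion[t_lv, c_lv] += 1
    n_calls = int(confusion.sum())
    acc = float(np.trace(confusion) / n_calls) if n_calls else float("nan")
    se = math.sqrt(acc * (1 - acc) / n_calls) if n_calls else float("nan")
    # representative boundary at the expected snapshot exposure
    if cfg.family == "binary":
        t_k = _expected_exposure(cfg)
        products = (weights[:, None] * rates).sum(axis=0) * t_k
    else:
        products = (weights[:, None] * np.asarray(cfg.kri_levels, float)).sum(
            axis=0
        ) * cfg.poisson_exposure
    cuts = _boundary_cutoffs(cfg, products)
    return SimResult(accuracy=acc, n_calls=n_calls, seed=seed, reps=reps,
                     mc_se=se, boundary_example=tuple(cuts), confusion=confusion)


def _expected_exposure(cfg: ScenarioConfig) -> float:
    T = cfg.monitoring_time
    if cfg.accrual <= 0:
        return min(T, cfg.followup) if cfg.followup > 0 else T
    lo = max(0.0, T - cfg.accrual)
    mean_exp = (lo + T) / 2.0  # uniform enrollment, conditioned on enrolled
    if cfg.followup > 0:
        mean_exp = min(mean_exp, cfg.followup)
    return mean_exp


def generate_subjects(cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw one replication as subject-level records plus true site levels.

    Returns ``(records, truth)``: a DataFrame in the internal subject
    format (site_id, kri_id, enrollment_time, censor_time, event_times,
    value) and a ``{site_id: true_level}`` mapping (1-based levels).
    Binary KRIs get exponential event times over the follow-up window;
    Poisson KRIs get event counts encoded as that many zero-duration event
    stamps spread over the exposure.
    """
    import pandas as pd

    truth = _truth_for_sites(cfg, rng)
    if cfg.n_sites == 1:
        sizes = np.array([cfg.total_n])
    else:
        sizes = rng.multinomial(cfg.total_n, cfg.site_size_probs)
    if cfg.family == "binary":
        tref = cfg.reference_time
        rates = np.array(
            [
                [bnd.proportion_to_rate(p, tref) if p > 0 else 0.0 for p in lv]
                for lv in cfg.kri_levels
            ]
        )
    horizon = cfg.followup if cfg.n_sites > 1 else cfg.horizon
    rows = []
    truth_out = {}
    for s in range(cfg.n_sites):
        sid = f"site_{s + 1:02d}"
        truth_out[sid] = int(truth[s]) + 1
        n_s = int(sizes[s])
        for i in range(n_s):
            enroll = float(rng.uniform(0, cfg.accrual)) if cfg.accrual > 0 else 0.0
            for j in range(len(cfg.kri_levels)):
                if cfg.family == "binary":
                    lam = rates[j, truth[s]]
                    t_ev = rng.exponential(1.0 / lam) if lam > 0 else math.inf
                    events = [round(t_ev, 4)] if t_ev <= horizon else []
                else:
                    t = cfg.poisson_exposure
                    k = int(rng.poisson(cfg.kri_levels[j][truth[s]] * t))
                    events = sorted(round(float(x), 4) for x in rng.uniform(0, t, k))
                    horizon = t
                rows.append(
                    {
                        "site_id": sid,
                        "kri_id": f"kri_{j + 1}",
                        "enrollment_time": round(enroll, 4),
                        "censor_time": horizon,
                        "event_times": events,
                        "value": None,
                    }
                )
    return pd.DataFrame(rows), truth_out


# ---------------------------------------------------------------------------
# Exact accuracy and boundary sweeps (single binary KRI, single site)
# ---------------------------------------------------------------------------


def analytic_accuracy(
    p_hi: float,
    p_lo: float,
    n: int,
    cutoff: float,
    mixture: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Exact site-classification accuracy of a proportion cutoff for a
    single binary KRI: ``w_hi P(X_hi > n c) + w_lo P(X_lo <= n c)`` with
    exact binomial CDFs.  Ties at the cutoff classify to the low-risk side.
    """
    if not (0 < p_lo < p_hi < 1):
        raise DomainError("need 0 < p_lo < p_hi < 1")
    if n < 1:
        raise DomainError("n must be >= 1")
    w_hi, w_lo = mixture
    k = math.floor(n * cutoff + 1e-12)
    return float(w_hi * stats.binom.sf(k, n, p_hi) + w_lo * stats.binom.cdf(k, n, p_lo))


def optimal_integer_cutoff(
    p_hi: float, p_lo: float, n: int, mixture: tuple[float, float] = (0.5, 0.5)
) -> int:
    """Argmax over integer cutoffs of :func:`analytic_accuracy` (full scan)."""
    accs = [
        (analytic_accuracy(p_hi, p_lo, n, k / n, mixture), -k) for k in range(n + 1)
    ]
    best = max(accs)
    return -best[1]


@dataclass
class SweepResult:
    candidates: np.ndarray
    sim_accuracy: np.ndarray
    analytic: np.ndarray
    proposed: float


def boundary_sweep(
    p_hi: float,
    p_lo: float,
    n: int,
    candidates: Sequence[float] | None = None,
    reps: int = 1000,
    seed: int = 0,
    mixture: tuple[float, float] = (0.5, 0.5),
    priors: tuple[float, float] = (1.0, 1.0),
) -> SweepResult:
    """Accuracy of every candidate proportion boundary for one binary KRI.

    Draws ``reps`` single-site replications (truth mixed per ``mixture``),
    classifies each against every candidate, and also reports the exact
    analytic accuracy; the proposed closed-form boundary is included.
    """
    proposed = bnd.binomial_boundary(p_hi, p_lo, n_k=n,
                                     prior_hi=priors[0], prior_lo=priors[1])
    if candidates is None:
        candidates = np.linspace(p_lo, p_hi, 41)
    cand = np.sort(np.unique(np.append(np.asarray(candidates, float), proposed)))
    rng = np.random.default_rng(seed)
    truth_hi = rng.random(reps) < mixture[0]
    x = np.where(
        truth_hi, rng.binomial(n, p_hi, reps), rng.binomial(n, p_lo, reps)
    )
    phat = x / n
    call_hi = phat[:, None] > cand[None, :]
    correct = call_hi == truth_hi[:, None]
    sim_acc = correct.mean(axis=0)
    analytic = np.array([analytic_accuracy(p_hi, p_lo, n, c, mixture) for c in cand])
    return SweepResult(candidates=cand, sim_accuracy=sim_acc,
                       analytic=analytic, proposed=proposed)


def median_comparison(
    p_hi: float,
    p_lo: float,
    ns: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Misclassification counts of the proposed boundary vs the midpoint
    (median) of the two level estimates, on identical draws.

    Returns per-``n`` simulated counts plus the exact expected counts from
    the binomial CDFs, and their totals across the sample sizes.
    """
    proposed = bnd.binomial_boundary(p_hi, p_lo)
    median = (p_hi + p_lo) / 2.0
    rng = np.random.default_rng(seed)
    out = {"proposed_boundary": proposed, "median": median, "per_n": {}}
    tot_sim = tot_exp = 0.0
    for n in ns:
        truth_hi = rng.random(reps) < 0.5
        x = np.where(truth_hi, rng.binomial(n, p_hi, reps),
                     rng.binomial(n, p_lo, reps))
        err_prop = int(((x / n > proposed) != truth_hi).sum())
        err_med = int(((x / n > median) != truth_hi).sum())
        exp_prop = reps * (1 - analytic_accuracy(p_hi, p_lo, n, proposed))
        exp_med = reps * (1 - analytic_accuracy(p_hi, p_lo, n, median))
        out["per_n"][n] = {
            "errors_proposed": err_prop,
            "errors_median": err_med,
            "saved": err_med - err_prop,
            "expected_saved": exp_med - exp_prop,
        }
        tot_sim += err_med - err_prop
        tot_exp += exp_med - exp_prop
    out["saved_total"] = int(tot_sim)
    out["expected_saved_total"] = float(tot_exp)
    return out


# ---------------------------------------------------------------------------
# Scenario presets (the published 12-scenario grid)
# ---------------------------------------------------------------------------

_SCEN1 = ((0.40, 0.10), (0.25, 0.04), (0.10, 0.01))
_SCEN2 = ((0.40, 0.25, 0.10), (0.30, 0.15, 0.04), (0.20, 0.05, 0.01))
_SCEN3 = ((0.20, 0.20), (0.20, 0.05), (0.05, 0.01))
_SCEN9 = ((7.0, 5.0), (4.0, 3.0), (1.0, 1.0))
_SCEN11 = ((0.25, 0.10),)
_SCEN12 = ((0.35, 0.15), (0.25, 0.10), (0.15, 0.05))

#: (accrual, followup) by (scenario, n) for the multicenter rows.
_ACCRUAL_FOLLOWUP = {
    (5, 20): (1, 3), (5, 50): (3, 7), (5, 80): (4, 8),
    (6, 120): (10, 10),
    (7, 160): (4, 8), (7, 200): (6, 12),
    (8, 200): (6, 12), (8, 400): (8, 16),
}


def scenario(number: int, n: int, monitoring: float | None = None,
             **overrides) -> ScenarioConfig:
    """Preset scenario configurations matching the published grid.

    Scenarios 1-4, 11, 12 are single-site (monitoring fraction required);
    5-10 are multicenter with fixed monitoring fractions.  Any field can be
    overridden by keyword.
    """
    if number in (1, 2, 3, 4, 11, 12):
        levels = {1: _SCEN1, 2: _SCEN2, 3: _SCEN3, 4: _SCEN3,
                  11: _SCEN11, 12: _SCEN12}[number]
        if monitoring is None:
            raise ConfigurationError("single-site scenarios need a monitoring fraction")
        alloc = (1,) * len(levels[0])
        cfg = ScenarioConfig(
            name=f"scenario_{number}", total_n=n, kri_levels=levels,
            allocation=alloc, monitoring_fraction=monitoring,
            weights=(0.10, 0.45, 0.45) if number == 4 else None,
        )
    elif number in (5, 6, 7, 8):
        a, f = _ACCRUAL_FOLLOWUP[(number, n)]
        five = number in (5, 6)
        cfg = ScenarioConfig(
            name=f"scenario_{number}", total_n=n, kri_levels=_SCEN1,
            n_sites=5 if five else 10,
            site_size_probs=SITE_WEIGHTS_5 if five else SITE_WEIGHTS_10,
            allocation=(2, 3) if five else (3, 2),
            accrual=a, followup=f,
            monitoring_fraction=monitoring or (0.33 if number in (5, 7) else 0.20),
        )
    elif number in (9, 10):
        five = number == 9
        cfg = ScenarioConfig(
            name=f"scenario_{number}", total_n=n, kri_levels=_SCEN9,
            family="poisson",
            n_sites=5 if five else 10,
            site_size_probs=SITE_WEIGHTS_5 if five else SITE_WEIGHTS_10,
            allocation=(2, 3) if five else (3, 2),
            monitoring_fraction=monitoring or (0.33 if five else 0.20),
        )
    else:
        raise ConfigurationError(f"unknown scenario {number}")
    return replace(cfg, **overrides) if overrides else cfg
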