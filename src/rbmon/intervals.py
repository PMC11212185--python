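"""Risk boundaries for interval hypotheses (average decision error rate).

The closed-form boundaries in :mod:`rbmon.boundaries` treat each risk level
as a point hypothesis (the site's rate *equals* the level estimate).  When
a level is instead a whole interval of rates -- "the site's Poisson rate
lies between lambda_g and lambda_{g-1}" -- the natural objective is the
*average* decision error rate: the error probability averaged over the
within-interval distribution of the rate (uniform by default) and over the
prior on levels.  No closed form exists; the optimal integer decision
cutoffs are found by exhaustive scan.

Only the Poisson observation model is implemented exactly; the top
interval needs an explicit upper cap because Poisson rates are unbounded.
A wide cap widens the top interval and pushes the top boundary up, which
is why interval boundaries are typically wider than their point-hypothesis
counterparts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .boundaries import ConfigurationError, DomainError, PriorSpec


@dataclass(frozen=True)
class IntervalHypothesisSpec:
    """G interval hypotheses on a Poisson rate.

    ``endpoints`` are the decreasing level endpoints ``lambda_1 > ... >
    lambda_G > 0``; hypothesis ``g`` is ``lambda_g <= rate < lambda_{g-1}``
    with ``lambda_0 = upper_cap``.  The within-interval density of the rate
    is uniform.
    """

    endpoints: tuple[float, ...]
    upper_cap: float
    priors: PriorSpec

    def __init__(
        self,
        endpoints: Sequence[float],
        upper_cap: float,
        priors: PriorSpec | None = None,
    ):
        endpoints = tuple(float(x) for x in endpoints)
        if len(endpoints) < 3:
            raise ConfigurationError(
                "interval hypotheses need G >= 3 levels; use the closed-form "
                "point-hypothesis boundaries for G = 2"
            )
        if any(x <= 0 for x in endpoints) or any(
            a >= b for a, b in zip(endpoints[1:], endpoints)
        ):
            raise ConfigurationError("endpoints must be strictly decreasing and > 0")
        if upper_cap <= endpoints[0]:
            raise ConfigurationError("upper_cap must exceed the largest endpoint")
        priors = priors or PriorSpec.noninformative(len(endpoints))
        if priors.n_levels != len(endpoints):
            raise ConfigurationError("prior has wrong number of levels")
        object.__setattr__(self, "endpoints", endpoints)
        object.__setattr__(self, "upper_cap", float(upper_cap))
        object.__setattr__(self, "priors", priors)

    @property
    def n_levels(self) -> int:
        return len(self.endpoints)

    def interval(self, g: int) -> tuple[float, float]:
        """(lower, upper) endpoints of level ``g`` (1-based, level 1 on top)."""
        lo = self.endpoints[g - 1]
        hi = self.upper_cap if g == 1 else self.endpoints[g - 2]
        return lo, hi


def _interval_count_pmf(spec: IntervalHypothesisSpec, taus: np.ndarray) -> np.ndarray:
    """P(tau | H_g) for each level g (rows) and count tau (columns).

    Mixing Poisson(rate) uniformly over rate in (a, b) gives the marginal
    pmf ``(PoisCDF(tau; a) - PoisCDF(tau; b)) / (b - a)`` -- the integral
    of the Poisson density in the rate evaluates to a difference of CDFs.
    """
    out = np.empty((spec.n_levels, taus.size))
    for g in range(1, spec.n_levels + 1):
        a, b = spec.interval(g)
        out[g - 1] = (stats.poisson.cdf(taus, a) - stats.poisson.cdf(taus, b)) / (b - a)
    return np.clip(out, 0.0, None)


def posterior_given_tau(tau: int, spec: IntervalHypothesisSpec) -> tuple[float, ...]:
    """Posterior masses Pr(H_g | tau) for an observed count ``tau``.

    Normalised over levels: the marginal of ``tau`` is the prior mixture of
    the per-interval uniform-mixed Poisson pmfs.
    """
    if tau < 0 or int(tau) != tau:
        raise DomainError("tau must be a non-negative integer")
    lik = _interval_count_pmf(spec, np.array([int(tau)]))[:, 0]
    w = np.asarray(spec.priors.normalized())
    joint = w * lik
    total = joint.sum()
    if total <= 0:
        raise DomainError("observed count has zero density under every level")
    return tuple(joint / total)


def average_error_rate(
    cutoffs: Sequence[int], spec: IntervalHypothesisSpec
) -> float:
    """Average decision error rate of a strictly decreasing integer cutoff
    vector ``(c_1 > ... > c_{G-1})``.

    The decision rule assigns level 1 when the count exceeds ``c_1``, level
    g when ``c_g < tau <= c_{g-1}``, and level G when ``tau <= c_{G-1}``.
    The returned value is ``1 - sum_g Pr(H_g) P(correct | H_g)`` with the
    count marginalised over the uniform within-interval rate.
    """
    G = spec.n_levels
    cutoffs = [int(c) for c in cutoffs]
    if len(cutoffs) != G - 1:
        raise ConfigurationError(f"need {G - 1} cutoffs, got {len(cutoffs)}")
    if any(a >= b for a, b in zip(cutoffs[1:], cutoffs)) :
        raise DomainError("cutoffs must be strictly decreasing")
    if cutoffs[-1] < -1:
        raise DomainError("cutoffs must be >= -1")
    w = spec.priors.normalized()
    correct = 0.0
    for g in range(1, G + 1):
        a, b = spec.interval(g)
        upper = math.inf if g == 1 else cutoffs[g - 2]
        lower = -1 if g == G else cutoffs[g - 1]
        # P(lower < tau <= upper | H_g) via the CDF-difference identity.
        p = _uniform_mixture_cdf(upper, a, b) - _uniform_mixture_cdf(lower, a, b)
        correct += w[g - 1] * p
    return float(min(max(1.0 - correct, 0.0), 1.0))


def _uniform_mixture_cdf(c: float, a: float, b: float) -> float:
    """P(tau <= c) when tau ~ Poisson(rate), rate ~ U(a, b)."""
    if c == math.inf:
        return 1.0
    if c < 0:
        return 0.0
    c = math.floor(c)
    # Integral of PoisCDF(c; rate) over rate: sum of CDF-difference terms.
    taus = np.arange(0, c + 1)
    pmf = (stats.poisson.cdf(taus, a) - stats.poisson.cdf(taus, b)) / (b - a)
    return float(np.clip(pmf, 0.0, None).sum())


@dataclass(frozen=True)
class IntervalBoundaries:
    """Result of the exhaustive cutoff scan."""

    cutoffs: tuple[int, ...]
    error_rate: float
    spec: IntervalHypothesisSpec


def optimize_interval_boundaries(
    spec: IntervalHypothesisSpec, search_max: int | None = None
) -> IntervalBoundaries:
    """Exhaustively scan strictly ordered integer cutoff vectors and return
    the one minimising :func:`average_error_rate`.

    ``search_max`` defaults to ``ceil(cap_midpoint + 10 * sqrt(...))`` of the
    top interval so the scan covers the plausible support.  Deterministic
    given the spec; ties resolve to the lexicographically smallest vector.
    """
    G = spec.n_levels
    if search_max is None:
        top = spec.endpoints[0]
        search_max = int(math.ceil(top + 10.0 * math.sqrt(top))) + 1
    if search_max < G - 1:
        raise ConfigurationError("search_max too small for the number of cutoffs")

    # Precompute per-level pmfs once; each candidate evaluates by cumsum.
    taus = np.arange(0, search_max + 1)
    pmf = _interval_count_pmf(spec, taus)  # (G, T)
    cdf = np.cumsum(pmf, axis=1)
    tail = 1.0 - cdf  # P(tau > c | H_g)
    w = np.asarray(spec.priors.normalized())

    best: tuple[float, tuple[int, ...]] | None = None
    # Candidate cutoffs ascending c_{G-1} < ... < c_1, then reversed.
    for combo in itertools.combinations(range(search_max + 1), G - 1):
        cuts = tuple(reversed(combo))
        correct = w[0] * tail[0, cuts[0]]
        for g in range(2, G):
            correct += w[g - 1] * (cdf[g - 1, cuts[g - 2]] - cdf[g - 1, cuts[g - 1]])
        correct += w[G - 1] * cdf[G - 1, cuts[G - 2]]
        err = 1.0 - correct
        key = (err, cuts)
        if best is None or key < best:
            best = key
    assert best is not None
    return IntervalBoundaries(cutoffs=best[1], error_rate=float(best[0]), spec=spec)
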