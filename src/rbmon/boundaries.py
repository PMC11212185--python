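"""Closed-form optimal risk boundaries for key risk indicators (KRIs).

A key risk indicator is a critical data element (discontinuation rate,
adverse-event incidence, a lab value ...) used to judge whether a clinical
trial site needs on-site monitoring.  Each KRI is given ``G`` ordered risk
levels with point estimates (level 1 = highest risk), and the boundary
between two adjacent levels is placed where the prior-weighted probability
of calling the site's risk level wrongly is minimised.  For Poisson,
Poisson-process, binomial, exponential and normal observation models this
minimiser has a closed form: a log prior-odds term plus a term driven only
by the two adjacent level estimates.  With equal prior masses the prior
term vanishes and the boundary always falls strictly between the two
estimates.

All times are in months; event rates are per subject per month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence


class DomainError(ValueError):
    """An input is outside the mathematical domain of a boundary formula."""


class ConfigurationError(ValueError):
    """A KRI specification or prior specification is inconsistent."""


Family = Literal["poisson", "poisson_process", "binomial", "exponential", "normal"]
Direction = Literal["higher_is_riskier", "lower_is_riskier"]

_FAMILIES = ("poisson", "poisson_process", "binomial", "exponential", "normal")

#: Scale on which a boundary lives, by family.
FAMILY_SCALE = {
    "poisson": "events_per_subject",
    "poisson_process": "count_per_subject_over_t",
    "binomial": "proportion",
    "exponential": "mean_time",
    "normal": "mean_value",
}


# ---------------------------------------------------------------------------
# Priors and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Prior masses Pr(H_g) over the G risk-level hypotheses.

    Masses need not sum to one: only ratios of adjacent masses enter the
    boundary formulas.  Use :meth:`normalized` when a proper prior is
    wanted for reporting.
    """

    masses: tuple[float, ...]

    def __init__(self, masses: Sequence[float]):
        masses = tuple(float(m) for m in masses)
        if len(masses) < 2:
            raise ConfigurationError("a prior needs at least two risk levels")
        if not all(math.isfinite(m) and m > 0 for m in masses):
            raise ConfigurationError("prior masses must be positive and finite")
        object.__setattr__(self, "masses", masses)

    @classmethod
    def noninformative(cls, g: int) -> "PriorSpec":
        """Equal mass on each of ``g`` levels."""
        return cls((1.0,) * g)

    @property
    def n_levels(self) -> int:
        return len(self.masses)

    def adjacent_ratio(self, g: int) -> float:
        """Pr(H_{g+1}) / Pr(H_g) for the pair below level ``g`` (1-based)."""
        return self.masses[g] / self.masses[g - 1]

    def normalized(self) -> tuple[float, ...]:
        s = sum(self.masses)
        return tuple(m / s for m in self.masses)


@dataclass(frozen=True)
class KRIWeights:
    """Per-KRI weights w_j >= 0 used identically on the boundary side and
    the observed side of a multi-KRI comparison."""

    weights: dict[str, float]

    def __init__(self, weights: dict[str, float]):
        weights = {str(k): float(v) for k, v in weights.items()}
        if any(w < 0 for w in weights.values()):
            raise ConfigurationError("KRI weights must be non-negative")
        if not any(w > 0 for w in weights.values()):
            raise ConfigurationError("at least one KRI weight must be positive")
        object.__setattr__(self, "weights", weights)

    def __getitem__(self, kri_id: str) -> float:
        return self.weights[kri_id]

    @classmethod
    def uniform(cls, kri_ids: Sequence[str]) -> "KRIWeights":
        return cls({k: 1.0 for k in kri_ids})


# ---------------------------------------------------------------------------
# Risk level specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskLevelSpec:
    """Ordered risk-level estimates for one KRI.

    ``levels`` is ordered by *risk*, highest risk first.  For proportion /
    rate families entries are floats; for the normal family entries are
    ``(mean, sd)`` pairs.  ``reference_time`` is the follow-up time (months)
    over which a proportion estimate was observed; it is required for
    time-adjustment of binomial levels.
    """

    kri_id: str
    family: Family
    levels: tuple
    reference_time: float | None = None
    direction: Direction = "higher_is_riskier"
    weight: float = 1.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.direction not in ("higher_is_riskier", "lower_is_riskier"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        levels = tuple(
            tuple(float(x) for x in lv) if isinstance(lv, (tuple, list)) else float(lv)
            for lv in self.levels
        )
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ConfigurationError("need at least two risk levels")
        if self.reference_time is not None and self.reference_time <= 0:
            raise ConfigurationError("reference_time must be positive")
        self._validate_values()

    # -- validation ---------------------------------------------------------

    def _validate_values(self) -> None:
        vals = self.level_values()
        if self.family == "binomial":
            if not all(0 < v < 1 for v in vals):
                raise DomainError("proportions must lie strictly in (0, 1)")
        elif self.family == "normal":
            for _, sd in self.levels:
                if sd <= 0:
                    raise DomainError("normal level SDs must be positive")
        else:
            if not all(v > 0 for v in vals):
                raise DomainError("rates must be positive")
        ordered = self._risk_ordered_values()
        if any(a >= b for a, b in zip(ordered[1:], ordered)):
            raise DomainError(
                f"risk level estimates for {self.kri_id!r} must be strictly "
                "monotone across levels (level 1 = highest risk)"
            )

    def level_values(self) -> tuple[float, ...]:
        """Scalar estimate per level (means for the normal family)."""
        if self.family == "normal":
            return tuple(mu for mu, _ in self.levels)
        return tuple(self.levels)

    def _risk_ordered_values(self) -> tuple[float, ...]:
        # After direction normalisation, level 1 must have the largest value.
        vals = self.level_values()
        if self.direction == "lower_is_riskier":
            return tuple(reversed(vals))
        return vals

    @property
    def n_levels(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# Boundary formulas (value-ordered inputs: hi > lo)
# ---------------------------------------------------------------------------


def _check_priors(prior_hi: float, prior_lo: float) -> None:
    if prior_hi <= 0 or prior_lo <= 0:
        raise DomainError("prior masses must be positive")


def poisson_boundary(
    lambda_hi: float, lambda_lo: float, prior_hi: float = 1.0, prior_lo: float = 1.0
) -> float:
    """Optimal boundary (events per subject per unit time) between two
    Poisson rates, ``lambda_hi > lambda_lo > 0``.

    The returned value is real, not floored; classification compares the
    observed mean event count with it directly.
    """
    _check_priors(prior_hi, prior_lo)
    if lambda_lo <= 0 or lambda_hi <= lambda_lo:
        raise DomainError(
            f"need lambda_hi > lambda_lo > 0, got {lambda_hi!r} <= {lambda_lo!r}"
        )
    log_ratio = math.log(lambda_hi) - math.log(lambda_lo)
    return math.log(prior_lo / prior_hi) / log_ratio + (lambda_hi - lambda_lo) / log_ratio


def poisson_process_boundary(
    level_products: Sequence[float],
    priors: PriorSpec | None = None,
    *,
    site_id: str | None = None,
    t_k: float | None = None,
) -> "BoundarySet":
    """Boundaries between adjacent levels of combined rate-times-exposure
    products ``lambda_g * t_k`` (decreasing in g).

    Returns a :class:`BoundarySet` on the count-per-subject-over-``t_k``
    scale, one boundary per adjacent level pair.
    """
    products = [float(x) for x in level_products]
    if len(products) < 2:
        raise ConfigurationError("need at least two level products")
    priors = priors or PriorSpec.noninformative(len(products))
    if priors.n_levels != len(products):
        raise ConfigurationError("prior has wrong number of levels")
    bounds = []
    for g in range(len(products) - 1):
        hi, lo = products[g], products[g + 1]
        bounds.append(poisson_boundary(hi, lo, priors.masses[g], priors.masses[g + 1]))
    return BoundarySet(
        site_id=site_id,
        family="poisson_process",
        scale="count_per_subject_over_t",
        boundaries=tuple(bounds),
        prior_used=priors,
        t_k=t_k,
    )


def binomial_boundary(
    p_hi: float,
    p_lo: float,
    n_k: int = 1,
    prior_hi: float = 1.0,
    prior_lo: float = 1.0,
) -> float:
    """Optimal boundary (proportion) between two binomial incidence
    proportions ``0 < p_lo < p_hi < 1`` for a site with ``n_k`` subjects.

    With equal prior masses the first term vanishes and the boundary does
    not depend on ``n_k``.
    """
    _check_priors(prior_hi, prior_lo)
    if not (0 < p_lo < p_hi < 1):
        raise DomainError(f"need 0 < p_lo < p_hi < 1, got p_hi={p_hi!r}, p_lo={p_lo!r}")
    if n_k < 1:
        raise DomainError("n_k must be >= 1")
    log_odds_ratio = math.log(p_hi * (1 - p_lo) / (p_lo * (1 - p_hi)))
    return (
        math.log(prior_lo / prior_hi) / (n_k * log_odds_ratio)
        + math.log((1 - p_lo) / (1 - p_hi)) / log_odds_ratio
    )


def exponential_boundary(
    lambda_hi: float, lambda_lo: float, prior_hi: float = 1.0, prior_lo: float = 1.0
) -> float:
    """Optimal boundary (mean event time) between two exponential hazard
    rates.  Observed mean times *below* the boundary indicate the
    higher-risk side; under equal priors it is the reciprocal of the
    Poisson boundary for the same rates.
    """
    _check_priors(prior_hi, prior_lo)
    if lambda_lo <= 0 or lambda_hi <= lambda_lo:
        raise DomainError(
            f"need lambda_hi > lambda_lo > 0, got {lambda_hi!r} <= {lambda_lo!r}"
        )
    diff = lambda_hi - lambda_lo
    return math.log(prior_lo / prior_hi) / diff + (
        math.log(lambda_hi) - math.log(lambda_lo)
    ) / diff


def normal_boundary(
    mu_hi: float,
    mu_lo: float,
    sigma2: float,
    prior_hi: float = 1.0,
    prior_lo: float = 1.0,
) -> float:
    """Optimal boundary (mean value) between two normal means with common
    variance ``sigma2``.  Under equal priors this is the midpoint of the
    two means, for every variance.
    """
    _check_priors(prior_hi, prior_lo)
    if mu_hi <= mu_lo:
        raise DomainError(f"need mu_hi > mu_lo, got {mu_hi!r} <= {mu_lo!r}")
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    return math.log(prior_lo / prior_hi) * sigma2 / (mu_hi - mu_lo) + (mu_hi + mu_lo) / 2


# ---------------------------------------------------------------------------
# Time adjustment and scale conversions
# ---------------------------------------------------------------------------


def proportion_to_rate(p: float, t: float) -> float:
    """Hazard rate implied by incidence proportion ``p`` over ``t`` months,
    assuming exponential event times: ``-ln(1 - p) / t``."""
    if t <= 0:
        raise DomainError("t must be positive")
    if not (0 <= p < 1):
        raise DomainError("p must lie in [0, 1); p = 1 implies an infinite rate")
    return -math.log1p(-p) / t


def rate_to_proportion(lam: float, t: float) -> float:
    """Incidence proportion over ``t`` months for hazard rate ``lam``:
    ``1 - exp(-lam * t)``."""
    if t <= 0:
        raise DomainError("t must be positive")
    if lam < 0:
        raise DomainError("rate must be non-negative")
    return -math.expm1(-lam * t)


def theta_to_pi(theta: float) -> float:
    """Convert a count boundary (Poisson process, once-only KRI) to a
    proportion boundary: ``pi* = 1 - exp(-theta)``."""
    if theta < 0:
        raise DomainError("theta must be non-negative")
    return -math.expm1(-theta)


def adjust_levels_for_time(spec: RiskLevelSpec, t_jk: float) -> RiskLevelSpec:
    """Re-express binomial risk-level proportions at a new follow-up time.

    Each level proportion observed over ``spec.reference_time`` is converted
    to a hazard rate and back to the proportion expected over ``t_jk``
    months of follow-up.  Ordering across levels is preserved.
    """
    if spec.family != "binomial":
        raise ConfigurationError("time adjustment applies to binomial levels")
    if spec.reference_time is None:
        raise ConfigurationError(
            f"KRI {spec.kri_id!r} has no reference_time; cannot adjust levels"
        )
    if t_jk <= 0:
        raise DomainError("t_jk must be positive")
    new_levels = tuple(
        rate_to_proportion(proportion_to_rate(p, spec.reference_time), t_jk)
        for p in spec.levels
    )
    return replace(spec, levels=new_levels, reference_time=t_jk)


# ---------------------------------------------------------------------------
# Multi-KRI combination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinedLevels:
    """Per-level parameters after combining several KRIs of one family."""

    family: Family
    values: tuple[float, ...]  # lambda_g * t_k products, p_g, or mu_g
    sigma2: float | None = None  # normal family only
    n_k: int | None = None  # binomial family only


def combine_weighted(
    specs: Sequence[RiskLevelSpec],
    weights: KRIWeights | None = None,
    t_per_kri: float | dict[str, float] = 1.0,
) -> CombinedLevels:
    """Weighted per-level combination of several same-family KRIs.

    For rate families the combined level-``g`` product is
    ``sum_j w_j * lambda_jg * t_jk``; for the normal family the combined
    mean is ``sum_j w_j * mu_jg`` with variance ``sum_j sigma_jg^2``.
    Binomial KRIs are only additive when every KRI shares the same
    per-level proportions; otherwise convert each proportion to a rate and
    use the Poisson-process path.
    """
    if not specs:
        raise ConfigurationError("need at least one KRI")
    family = specs[0].family
    if any(s.family != family for s in specs):
        raise ConfigurationError("cannot combine KRIs of mixed families")
    weights = weights or KRIWeights.uniform([s.kri_id for s in specs])
    G = specs[0].n_levels
    if any(s.n_levels != G for s in specs):
        raise ConfigurationError("all KRIs must share the same number of levels")

    def t_of(s: RiskLevelSpec) -> float:
        if isinstance(t_per_kri, dict):
            return float(t_per_kri[s.kri_id])
        return float(t_per_kri)

    if family == "binomial":
        for g in range(G):
            vals = {s.levels[g] for s in specs}
            if len(vals) > 1:
                raise ConfigurationError(
                    "binomial KRIs with unequal per-level proportions are not "
                    "additive; convert with proportion_to_rate and combine on "
                    "the Poisson-process scale"
                )
        return CombinedLevels(family="binomial", values=specs[0].level_values())

    if family == "normal":
        mus = tuple(
            sum(weights[s.kri_id] * s.levels[g][0] for s in specs) for g in range(G)
        )
        sigma2 = sum(s.levels[0][1] ** 2 for s in specs)
        _check_ordering(mus)
        return CombinedLevels(family="normal", values=mus, sigma2=sigma2)

    # poisson / poisson_process / exponential rates
    products = tuple(
        sum(weights[s.kri_id] * s.levels[g] * t_of(s) for s in specs) for g in range(G)
    )
    _check_ordering(products)
    return CombinedLevels(family=family, values=products)


def _check_ordering(values: Sequence[float]) -> None:
    if any(a >= b for a, b in zip(values[1:], values)):
        raise DomainError("combined level values are not strictly decreasing")


def euclidean_weights(specs: Sequence[RiskLevelSpec]) -> KRIWeights:
    """Data-driven weights proportional to the gap between neighbouring
    risk-level estimates of each KRI.

    The per-KRI distance is the Euclidean distance between adjacent-level
    estimate vectors (for G > 2, the mean over adjacent pairs); weights are
    normalised to sum to the number of KRIs, so a lone KRI gets weight 1.
    """
    if not specs:
        raise ConfigurationError("need at least one KRI")
    family = specs[0].family
    if any(s.family != family for s in specs):
        raise ConfigurationError("cannot weight KRIs of mixed families")
    dists = []
    for s in specs:
        vals = s.level_values()
        gaps = [abs(a - b) for a, b in zip(vals, vals[1:])]
        dists.append(sum(gaps) / len(gaps))
    total = sum(dists)
    if total == 0:
        raise ConfigurationError("all adjacent level estimates are identical")
    J = len(specs)
    return KRIWeights({s.kri_id: J * d / total for s, d in zip(specs, dists)})


# ---------------------------------------------------------------------------
# Boundary sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundarySet:
    """The G-1 optimal boundaries for one site (or the whole trial).

    ``boundaries[g-1]`` separates level ``g`` from level ``g+1``.  For
    scales where larger observed values mean more risk the boundaries are
    decreasing; the exponential mean-time scale is reversed.
    """

    family: Family
    scale: str
    boundaries: tuple[float, ...]
    prior_used: PriorSpec
    site_id: str | None = None
    n_k: int | None = None
    t_k: float | None = None
    direction: Direction = "higher_is_riskier"

    @property
    def n_levels(self) -> int:
        return len(self.boundaries) + 1

    @property
    def riskier_side(self) -> str:
        """Which side of a boundary is the higher-risk side for an
        observed statistic."""
        reversed_scale = self.scale == "mean_time"
        reversed_dir = self.direction == "lower_is_riskier"
        return "below" if (reversed_scale ^ reversed_dir) else "above"


def boundary_set(
    levels: RiskLevelSpec | CombinedLevels,
    priors: PriorSpec | None = None,
    *,
    n_k: int = 1,
    t_k: float = 1.0,
    site_id: str | None = None,
) -> BoundarySet:
    """Compute all adjacent-pair boundaries for a single KRI or a combined
    multi-KRI level set.

    ``t_k`` multiplies rates for the Poisson-process scale; ``n_k`` enters
    the binomial prior term.  Direction handling: level estimates ordered
    by risk are fed to the formulas value-ordered, and for
    ``lower_is_riskier`` KRIs the comparison operator is inverted at
    classification time instead.
    """
    direction: Direction = "higher_is_riskier"
    if isinstance(levels, RiskLevelSpec):
        family = levels.family
        values = levels.level_values()
        sigma2 = sum(sd**2 for _, sd in levels.levels) if family == "normal" else None
        direction = levels.direction
    else:
        family = levels.family
        values = levels.values
        sigma2 = levels.sigma2
        if levels.n_k is not None:
            n_k = levels.n_k
    G = len(values)
    priors = priors or PriorSpec.noninformative(G)
    if priors.n_levels != G:
        raise ConfigurationError("prior has wrong number of levels")

    # Value-ordered inputs: for lower_is_riskier the risk ordering is the
    # reverse of the value ordering, so flip values and priors together.
    masses = priors.masses
    if direction == "lower_is_riskier":
        values = tuple(reversed(values))
        masses = tuple(reversed(masses))

    bounds = []
    for g in range(G - 1):
        hi, lo = values[g], values[g + 1]
        m_hi, m_lo = masses[g], masses[g + 1]
        if family == "binomial":
            b = binomial_boundary(hi, lo, n_k=n_k, prior_hi=m_hi, prior_lo=m_lo)
        elif family == "exponential":
            b = exponential_boundary(hi, lo, prior_hi=m_hi, prior_lo=m_lo)
        elif family == "normal":
            b = normal_boundary(hi, lo, sigma2, prior_hi=m_hi, prior_lo=m_lo)
        elif family == "poisson_process":
            b = poisson_boundary(hi * t_k, lo * t_k, prior_hi=m_hi, prior_lo=m_lo)
        else:  # poisson
            b = poisson_boundary(hi, lo, prior_hi=m_hi, prior_lo=m_lo)
        bounds.append(b)
    if direction == "lower_is_riskier":
        bounds = list(reversed(bounds))
    return BoundarySet(
        family=family,
        scale=FAMILY_SCALE[family],
        boundaries=tuple(bounds),
        prior_used=priors,
        site_id=site_id,
        n_k=n_k if family == "binomial" else None,
        t_k=t_k if family == "poisson_process" else None,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Specified-rule level setting (offset rules)
# ---------------------------------------------------------------------------


def levels_from_overall(
    overall: float,
    offsets: Sequence[float],
    direction: Direction = "higher_is_riskier",
) -> tuple[float, ...]:
    """Risk-level estimates from an overall rate plus absolute offsets.

    A common specified rule sets, e.g., the high-risk discontinuation level
    at the all-site average plus 30 percentage points and the medium level
    at plus 15 points; for a KRI where suspiciously *low* values are risky
    (under-reported adverse events) the offsets are subtracted instead.
    Offsets must be given largest first; returned levels are ordered
    highest risk first.
    """
    offs = [float(o) for o in offsets]
    if any(a >= b for a, b in zip(offs[1:], offs)):
        raise ConfigurationError("offsets must be strictly decreasing")
    if direction == "higher_is_riskier":
        return tuple(overall + o for o in offs)
    return tuple(overall - o for o in offs)
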