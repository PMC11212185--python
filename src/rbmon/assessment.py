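"""Site-level risk assessment from subject-level monitoring extracts.

Turns subject records into per-site monitoring snapshots, classifies the
observed KRI statistic against a boundary set, applies monitoring-action
labels, votes across KRIs, and assesses risk within calendar or study-day
time windows with a traffic-light display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import boundaries as bnd
from .boundaries import (
    BoundarySet,
    ConfigurationError,
    DomainError,
    KRIWeights,
    PriorSpec,
    RiskLevelSpec,
)

log = logging.getLogger("rbmon")

#: Default monitoring actions for three risk levels (level 1 first).
DEFAULT_ACTIONS_G3 = ("on-site monitoring required",
                      "on-site monitoring recommended",
                      "on-site monitoring unnecessary")
DEFAULT_ACTIONS_G2 = ("on-site monitoring required",
                      "on-site monitoring unnecessary")

TRAFFIC_COLORS = {"high": "red", "mid": "amber", "low": "green"}


def action_labels(G: int) -> tuple[str, ...]:
    if G == 2:
        return DEFAULT_ACTIONS_G2
    if G == 3:
        return DEFAULT_ACTIONS_G3
    return tuple(f"risk level {g}" for g in range(1, G + 1))


def level_color(level: int, G: int) -> str:
    """Traffic-light color: level 1 red, level G green, the rest amber."""
    if level == 1:
        return "red"
    if level == G:
        return "green"
    return "amber"


# ---------------------------------------------------------------------------
# Subject records and snapshots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observation for one KRI.

    Times are months; ``enrollment_time`` is measured from trial start and
    ``event_times`` / ``censor_time`` from the subject's own enrollment
    (first dose).
    """

    site_id: str
    kri_id: str
    enrollment_time: float
    censor_time: float
    event_times: tuple[float, ...] = ()
    value: float | None = None

    def __post_init__(self):
        if self.enrollment_time < 0 or self.censor_time < 0:
            raise DomainError("times must be non-negative")
        ev = tuple(sorted(float(t) for t in self.event_times))
        if any(t < 0 for t in ev):
            raise DomainError("event times must be non-negative")
        if any(t > self.censor_time for t in ev):
            raise DomainError("event times cannot exceed the censor time")
        object.__setattr__(self, "event_times", ev)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "kri_id": [r.kri_id for r in records],
            "enrollment_time": [r.enrollment_time for r in records],
            "censor_time": [r.censor_time for r in records],
            "event_times": [list(r.event_times) for r in records],
            "value": [r.value for r in records],
        }
    )


@dataclass(frozen=True)
class MonitoringSnapshot:
    """Per-site observed KRI summaries at a monitoring time.

    ``e_hat`` is the family statistic: events per subject for count
    families, the observed incidence proportion for once-only KRIs, or the
    mean value for continuous KRIs.  ``t_jk`` is the mean exposure in
    months; ``event_fraction`` and ``quantile_time`` support the
    exponential (time-to-event) comparison.
    """

    site_id: str
    kri_id: str
    n: int
    e_hat: float
    t_jk: float
    total_events: int = 0
    event_fraction: float = float("nan")
    quantile_time: float = float("nan")
    empty: bool = False


def summarize_site(
    records: Sequence[SubjectRecord] | pd.DataFrame,
    monitoring_time: float,
    family: str,
    *,
    site_id: str | None = None,
    kri_id: str | None = None,
) -> MonitoringSnapshot:
    """Summarise one site's records for one KRI at ``monitoring_time``.

    Only subjects enrolled strictly before the monitoring time contribute;
    each contributes exposure ``min(censor_time, monitoring_time -
    enrollment_time)`` and the events that fall inside that exposure.  A
    site with no enrolled subjects yields a flagged empty snapshot rather
    than an exception, so it can be excluded downstream.
    """
    if monitoring_time <= 0:
        raise DomainError("monitoring_time must be positive")
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    if site_id is not None:
        records = records[records["site_id"] == site_id]
    if kri_id is not None:
        records = records[records["kri_id"] == kri_id]
    sid = site_id or (records["site_id"].iloc[0] if len(records) else "?")
    kid = kri_id or (records["kri_id"].iloc[0] if len(records) else "?")

    enrolled = records[records["enrollment_time"] < monitoring_time]
    n = len(enrolled)
    if n == 0:
        return MonitoringSnapshot(sid, kid, 0, float("nan"), float("nan"), empty=True)

    exposure = np.minimum(
        enrolled["censor_time"].to_numpy(float),
        monitoring_time - enrolled["enrollment_time"].to_numpy(float),
    )
    events_in = [
        [t for t in ev if t <= ex]
        for ev, ex in zip(enrolled["event_times"], exposure)
    ]
    counts = np.array([len(e) for e in events_in])
    total = int(counts.sum())
    t_jk = float(exposure.mean())

    if family == "normal":
        vals = enrolled["value"].astype(float)
        e_hat = float(vals.mean())
    elif family == "binomial":
        e_hat = float((counts > 0).mean())
    elif family == "poisson":
        e_hat = total / float(exposure.sum())  # events per subject-month
    else:  # poisson_process / exponential: events per subject over t_jk
        e_hat = total / n

    frac = float((counts > 0).mean())
    qt = float("nan")
    first_times = sorted(e[0] for e in events_in if e)
    if first_times:
        qt = float(first_times[-1])  # observed event_fraction-quantile time
    return MonitoringSnapshot(
        sid, kid, n, e_hat, t_jk,
        total_events=total, event_fraction=frac, quantile_time=qt,
    )


def combine_snapshots(
    snaps: Sequence[MonitoringSnapshot], weights: KRIWeights | None = None
) -> float:
    """Weighted combined statistic ``E_k = sum_j w_j E_jk`` across KRIs."""
    live = [s for s in snaps if not s.empty]
    if not live:
        raise ConfigurationError("no non-empty snapshots to combine")
    weights = weights or KRIWeights.uniform([s.kri_id for s in live])
    return float(sum(weights[s.kri_id] * s.e_hat for s in live))


# ---------------------------------------------------------------------------
# Classification and decision rules
# ---------------------------------------------------------------------------


def classify(statistic: float, bset: BoundarySet) -> int:
    """Assign a risk level (1..G) to an observed statistic.

    For scales where larger values mean more risk: at or below the lowest
    boundary is level G, above the highest boundary is level 1, and a tie
    at a boundary goes to the lower-risk side.  The exponential mean-time
    scale (and ``lower_is_riskier`` KRIs) use the reversed comparator.
    """
    if not math.isfinite(statistic):
        raise DomainError("statistic must be finite")
    G = bset.n_levels
    if bset.riskier_side == "above":
        for g, b in enumerate(bset.boundaries, start=1):
            if statistic > b:
                return g
        return G
    for g, b in enumerate(bset.boundaries, start=1):
        if statistic < b:
            return g
    return G


def per_kri_vote(levels: Sequence[int], *, at_or_above: int = 1, count: int = 1) -> bool:
    """Trigger an action when at least ``count`` KRIs sit at risk level
    ``at_or_above`` or riskier (numerically smaller level)."""
    if count < 1:
        raise ConfigurationError("vote count must be >= 1")
    if count > len(levels):
        raise ConfigurationError(
            f"vote needs {count} KRIs but only {len(levels)} were assessed"
        )
    return sum(1 for lv in levels if lv <= at_or_above) >= count


def exponential_time_threshold(
    e_boundary: float,
    event_fraction: float,
    convention: Literal["literal", "survival_quantile"] = "literal",
) -> float:
    """Time threshold for comparing an observed quantile survival time with
    an exponential mean-time boundary.

    The literal convention multiplies by ``-ln(event_fraction)``; the
    survival-quantile convention, which treats the event fraction as the
    quantile of the event-time distribution, uses ``-ln(1 -
    event_fraction)``.  The two coincide at an event fraction of one half.
    Observed quantile times below the threshold indicate the riskier side.
    """
    if not (0 < event_fraction < 1):
        raise DomainError("event_fraction must lie strictly between 0 and 1")
    if convention == "literal":
        return e_boundary * -math.log(event_fraction)
    if convention == "survival_quantile":
        return e_boundary * -math.log1p(-event_fraction)
    raise ConfigurationError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Whole-site assessment
# ---------------------------------------------------------------------------


@dataclass
class SiteAssessment:
    site_id: str
    statistic: float
    bset: BoundarySet
    level: int
    action: str
    color: str
    per_kri_levels: dict[str, int] = field(default_factory=dict)
    window: tuple[float, float] | None = None
    n: int = 0
    t_k: float = float("nan")


def _equal_level_proportions(specs: Sequence[RiskLevelSpec]) -> bool:
    first = specs[0]
    return all(
        s.levels == first.levels and s.direction == first.direction for s in specs
    )


def assess_site(
    records: pd.DataFrame,
    specs: Sequence[RiskLevelSpec],
    monitoring_time: float,
    *,
    priors: PriorSpec | None = None,
    weights: KRIWeights | None = None,
    site_id: str | None = None,
) -> SiteAssessment | None:
    """Snapshot -> boundary -> level for one site, combining KRIs on the
    Poisson-process scale (binomial levels are first converted to rates
    using their reference times).

    Returns ``None`` for a site with no enrolled subjects.
    """
    sid = site_id or records["site_id"].iloc[0]
    fam = specs[0].family
    snaps = [
        summarize_site(records, monitoring_time,
                       "binomial" if fam == "binomial" else fam,
                       site_id=sid, kri_id=s.kri_id)
        for s in specs
    ]
    live = [s for s in snaps if not s.empty and s.n > 0]
    if not live:
        return None
    t_k = float(np.mean([s.t_jk for s in live]))
    weights = weights or KRIWeights.uniform([s.kri_id for s in specs])

    if fam == "normal":
        combined = bnd.combine_weighted(specs, weights)
        bset = bnd.boundary_set(combined, priors, site_id=sid)
        stat = combine_snapshots(
            [s for s in snaps if not s.empty], weights
        )
    elif fam == "binomial" and _equal_level_proportions(specs):
        # Once-only KRIs with shared per-level proportions pool into a
        # single binomial comparison on the proportion scale.
        adj = bnd.adjust_levels_for_time(specs[0], t_k)
        n_pool = sum(s.n for s in live)
        bset = bnd.boundary_set(adj, priors, n_k=n_pool, site_id=sid)
        stat = float(sum(s.n * s.e_hat for s in live) / n_pool)
    else:
        # Unequal binomial proportions (or count KRIs): combine on the
        # Poisson-process scale via the rate conversion.
        rate_specs = []
        for s in specs:
            if s.family == "binomial":
                tref = s.reference_time
                if tref is None:
                    raise ConfigurationError(
                        f"KRI {s.kri_id!r} needs reference_time for rate conversion"
                    )
                rates = tuple(bnd.proportion_to_rate(p, tref) for p in s.levels)
                rate_specs.append(
                    RiskLevelSpec(s.kri_id, "poisson_process", rates,
                                  direction=s.direction, weight=s.weight)
                )
            else:
                rate_specs.append(s)
        combined = bnd.combine_weighted(rate_specs, weights, t_per_kri=t_k)
        bset = bnd.boundary_set(combined, priors, t_k=t_k, site_id=sid)
        stat = float(
            sum(weights[s.kri_id] * s.total_events for s in live)
            / max(s.n for s in live)
        )
    level = classify(stat, bset)
    G = bset.n_levels
    per_kri = {}
    for s, snap in zip(specs, snaps):
        if snap.empty:
            continue
        single = bnd.boundary_set(
            s if s.family != "binomial" else bnd.adjust_levels_for_time(s, snap.t_jk),
            priors, t_k=snap.t_jk, site_id=sid,
        )
        per_kri[s.kri_id] = classify(snap.e_hat, single)
    return SiteAssessment(
        site_id=sid, statistic=stat, bset=bset, level=level,
        action=action_labels(G)[level - 1], color=level_color(level, G),
        per_kri_levels=per_kri, n=max(s.n for s in live), t_k=t_k,
    )


def assess_trial(
    records: pd.DataFrame,
    specs: Sequence[RiskLevelSpec],
    monitoring_time: float,
    *,
    priors: PriorSpec | None = None,
    weights: KRIWeights | None = None,
) -> list[SiteAssessment]:
    """Assess every site present in ``records``; empty sites are skipped."""
    out = []
    for sid, grp in records.groupby("site_id", sort=True):
        a = assess_site(grp, specs, monitoring_time,
                        priors=priors, weights=weights, site_id=str(sid))
        if a is None:
            log.info("site %s has no enrolled subjects; excluded", sid)
            continue
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# Time-windowed assessment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-duration assessment windows.

    ``calendar`` windows cut trial time (origin = trial start) so that,
    e.g., a pandemic-era discontinuation spike shows up in the windows it
    actually happened in; ``study_day`` windows cut each subject's own time
    axis from first dose, which suits exposure-dependent adverse events.
    ``duration`` is in days (converted internally to months of 30.4375 d).
    """

    mode: Literal["calendar", "study_day"]
    duration_days: float

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ConfigurationError("window duration must be positive")
        if self.mode not in ("calendar", "study_day"):
            raise ConfigurationError(f"unknown window mode {self.mode!r}")

    @property
    def duration_months(self) -> float:
        return self.duration_days / 30.4375


def _window_slice(
    records: pd.DataFrame, wspec: WindowSpec, w0: float, w1: float
) -> pd.DataFrame:
    """Clip records to one window, re-expressing exposure and event times
    relative to the window start so they can be summarised as usual."""
    rows = []
    for _, r in records.iterrows():
        if wspec.mode == "study_day":
            lo, hi = w0, w1
        else:  # calendar: subject time axis shifted by enrollment
            lo, hi = w0 - r["enrollment_time"], w1 - r["enrollment_time"]
        start = max(lo, 0.0)
        stop = min(hi, r["censor_time"])
        if stop <= start:
            continue
        events = [t - start for t in r["event_times"] if start < t <= stop]
        rows.append(
            {
                "site_id": r["site_id"],
                "kri_id": r["kri_id"],
                "enrollment_time": 0.0,
                "censor_time": stop - start,
                "event_times": events,
                "value": r["value"] if "value" in r else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "kri_id", "enrollment_time", "censor_time",
                 "event_times", "value"],
    )


def window_assess(
    records: pd.DataFrame,
    wspec: WindowSpec,
    specs: Sequence[RiskLevelSpec],
    *,
    horizon: float | None = None,
    priors_per_window: dict[int, PriorSpec] | None = None,
    priors: PriorSpec | None = None,
    weights: KRIWeights | None = None,
) -> list[SiteAssessment]:
    """Assess each site separately within fixed-duration windows.

    Returns one :class:`SiteAssessment` per (site, window) with a
    traffic-light color; empty windows are omitted with a logged notice.
    Windows may carry window-specific priors, e.g. down-weighting the
    high-risk hypothesis in a window where an external shock (a pandemic
    wave) is known to have inflated the KRI.
    """
    if horizon is None:
        if wspec.mode == "calendar":
            horizon = float((records["enrollment_time"] + records["censor_time"]).max())
        else:
            horizon = float(records["censor_time"].max())
    dur = wspec.duration_months
    n_windows = max(1, math.ceil(horizon / dur - 1e-9))
    out: list[SiteAssessment] = []
    for i in range(n_windows):
        w0, w1 = i * dur, (i + 1) * dur
        sliced = _window_slice(records, wspec, w0, w1)
        if sliced.empty:
            log.info("window %d (%.2f-%.2f mo) has no exposure; omitted", i, w0, w1)
            continue
        wpriors = (priors_per_window or {}).get(i, priors)
        for a in assess_trial(sliced, specs, monitoring_time=w1 - w0 + 1e-9,
                              priors=wpriors, weights=weights):
            a.window = (w0, w1)
            out.append(a)
    return out


def assessments_to_frame(assessments: Sequence[SiteAssessment]) -> pd.DataFrame:
    """Flatten assessments into the report table written by the CLI."""
    rows = []
    for a in assessments:
        rows.append(
            {
                "site_id": a.site_id,
                "window_start": a.window[0] if a.window else float("nan"),
                "window_end": a.window[1] if a.window else float("nan"),
                "n": a.n,
                "t_k": round(a.t_k, 4) if math.isfinite(a.t_k) else a.t_k,
                "statistic": round(a.statistic, 6),
                "boundaries": ";".join(f"{b:.6f}" for b in a.bset.boundaries),
                "scale": a.bset.scale,
                "level": a.level,
                "color": a.color,
                "action": a.action,
            }
        )
    return pd.DataFrame(rows)
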