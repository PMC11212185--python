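"""Funnel-plot control limits for site proportions (comparator method).

A funnel plot draws each site's observed incidence proportion against its
size together with control limits around the all-site proportion.  The
limits here are exact (conservative) binomial tail inversions, so they
widen sharply as the site size shrinks -- the feature that lets small
sites carry high observed proportions without being flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .boundaries import DomainError


def funnel_thresholds(p_bar: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial (lower, upper) observed-proportion limits for a site
    of size ``n`` under the overall proportion ``p_bar``.

    ``upper`` is the smallest x/n with ``P(X >= x) <= (1-conf)/2`` and
    ``lower`` the largest x/n with ``P(X <= x) <= (1-conf)/2`` (0 when no x
    qualifies); sites outside ``[lower, upper]`` are flagged.  Tail
    inversion makes the nominal coverage conservative.
    """
    if not (0 < p_bar < 1):
        raise DomainError("p_bar must lie strictly in (0, 1)")
    if not (0 < conf < 1):
        raise DomainError("conf must lie strictly in (0, 1)")
    if n < 1:
        raise DomainError("n must be >= 1")
    alpha = (1.0 - conf) / 2.0
    xs = np.arange(0, n + 1)
    upper_tail = stats.binom.sf(xs - 1, n, p_bar)  # P(X >= x)
    lower_tail = stats.binom.cdf(xs, n, p_bar)  # P(X <= x)
    up_candidates = xs[upper_tail <= alpha]
    lo_candidates = xs[lower_tail <= alpha]
    upper = float(up_candidates[0]) / n if up_candidates.size else 1.0
    lower = float(lo_candidates[-1]) / n if lo_candidates.size else 0.0
    return lower, upper


@dataclass(frozen=True)
class FunnelCurve:
    """Funnel limits tabulated over a grid of site sizes."""

    p_bar: float
    conf: float
    n_grid: tuple[int, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]


def funnel_curve(p_bar: float, n_grid: Sequence[int], conf: float = 0.95) -> FunnelCurve:
    lows, ups = zip(*(funnel_thresholds(p_bar, int(n), conf) for n in n_grid))
    return FunnelCurve(p_bar=p_bar, conf=conf, n_grid=tuple(int(n) for n in n_grid),
                       lower=lows, upper=ups)


def flag_sites(
    observed: Sequence[tuple[int, int]], p_bar: float, conf: float = 0.95
) -> list[bool]:
    """Flag sites whose observed proportion falls outside the exact limits.

    ``observed`` holds (events, n) pairs.
    """
    out = []
    for x, n in observed:
        lo, up = funnel_thresholds(p_bar, n, conf)
        p = x / n
        out.append(p < lo or p > up)
    return out
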