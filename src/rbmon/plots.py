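"""Plot helpers: funnel overlays and traffic-light matrices."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .assessment import SiteAssessment
from .funnel import FunnelCurve

_COLOR = {"red": "#d62728", "amber": "#ff9f1c", "green": "#2a9d3f"}


def funnel_plot(
    curve: FunnelCurve,
    sites: Sequence[tuple[int, float]] | None = None,
    boundaries: dict[str, float] | None = None,
    path: str | None = None,
):
    """Sites as points over size, with funnel limits and optional
    horizontal risk-boundary lines overlaid."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.n_grid, curve.upper, "b--", lw=1, label=f"funnel {curve.conf:.1%}")
    ax.plot(curve.n_grid, curve.lower, "b--", lw=1)
    ax.axhline(curve.p_bar, color="black", lw=1, label="overall proportion")
    if boundaries:
        for name, b in boundaries.items():
            ax.axhline(b, lw=1.2, label=name)
    if sites:
        ns, ps = zip(*sites)
        ax.scatter(ns, ps, s=18, color="#444", zorder=3, label="sites")
    ax.set_xlabel("site size (subjects)")
    ax.set_ylabel("observed proportion")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def traffic_light_plot(assessments: Sequence[SiteAssessment], path: str | None = None):
    """Matrix of (site x window) cells coloured red/amber/green."""
    sites = sorted({a.site_id for a in assessments})
    windows = sorted({a.window for a in assessments if a.window})
    if not windows:
        windows = [None]
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(windows), 0.6 + 0.25 * len(sites)))
    for a in assessments:
        i = sites.index(a.site_id)
        j = windows.index(a.window) if a.window else 0
        ax.add_patch(plt.Rectangle((j, i), 1, 1, color=_COLOR[a.color]))
    ax.set_xlim(0, len(windows))
    ax.set_ylim(0, len(sites))
    ax.set_yticks([i + 0.5 for i in range(len(sites))], sites, fontsize=6)
    labels = [f"{w[0]:.0f}-{w[1]:.0f}" if w else "all" for w in windows]
    ax.set_xticks([j + 0.5 for j in range(len(windows))], labels, fontsize=7)
    ax.set_xlabel("window (months)")
    ax.invert_yaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
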