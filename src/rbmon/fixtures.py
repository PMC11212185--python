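"""Synthetic multi-site trial fixtures.

`make_fixture("example_like", ...)` builds a synthetic stand-in for the
kind of Phase III multicenter oncology trial used to demonstrate the
method in practice: a few dozen sites of heterogeneous size, a once-only
discontinuation KRI (overall incidence ~25%) and three adverse-event KRIs
(overall incidence ~22%), with a handful of sites planted at a high
discontinuation rate and a handful of under-reporting sites with
suppressed AE incidence.  The data are simulated, not derived from any
real trial extract; a ground-truth sidecar table records each site's
planted risk class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundaries import ConfigurationError, proportion_to_rate

AE_KRIS = ("dry_skin", "diarrhoea", "paronychia")


@dataclass
class Fixture:
    records: pd.DataFrame  # internal subject format (see rbmon.io)
    truth: pd.DataFrame  # site_id, n, disc_class, ae_class, p_disc, p_ae


def make_fixture(
    kind: str = "example_like",
    seed: int = 0,
    n_sites: int = 50,
    overall_disc: float = 0.25,
    overall_ae: float = 0.222,
    high_disc_rate: float = 0.55,
    low_ae_rate: float = 0.02,
    n_high_disc: int = 3,
    n_low_ae: int = 3,
    accrual: float = 12.0,
    followup: float = 12.0,
) -> Fixture:
    """Generate a synthetic example-like trial.

    Most sites sit at the overall incidence; ``n_high_disc`` sites are
    planted above the high-risk discontinuation level and ``n_low_ae``
    sites under-report AEs.  Event times are exponential with rates
    implied by the incidence proportions over the follow-up period.
    """
    if kind != "example_like":
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(4, 31, size=n_sites)
    planted = rng.choice(n_sites, size=n_high_disc + n_low_ae, replace=False)
    high_disc = set(planted[:n_high_disc].tolist())
    low_ae = set(planted[n_high_disc:].tolist())

    rows = []
    truth_rows = []
    for s in range(n_sites):
        sid = f"site_{s + 1:02d}"
        n_s = int(sizes[s])
        p_disc = high_disc_rate if s in high_disc else overall_disc
        p_ae = low_ae_rate if s in low_ae else overall_ae
        lam_disc = proportion_to_rate(p_disc, followup)
        lam_ae = proportion_to_rate(p_ae, followup) if p_ae > 0 else 0.0
        enroll = rng.uniform(0.0, accrual, n_s)
        for i in range(n_s):
            for kri, lam in [("discontinuation", lam_disc)] + [
                (k, lam_ae) for k in AE_KRIS
            ]:
                t_ev = rng.exponential(1.0 / lam) if lam > 0 else np.inf
                events = [round(float(t_ev), 4)] if t_ev <= followup else []
                rows.append(
                    {
                        "site_id": sid,
                        "kri_id": kri,
                        "enrollment_time": round(float(enroll[i]), 4),
                        "censor_time": followup,
                        "event_times": events,
                        "value": None,
                    }
                )
        truth_rows.append(
            {
                "site_id": sid,
                "n": n_s,
                "disc_class": "high" if s in high_disc else "typical",
                "ae_class": "under_reporting" if s in low_ae else "typical",
                "p_disc": p_disc,
                "p_ae": p_ae,
            }
        )
    return Fixture(records=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows))
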