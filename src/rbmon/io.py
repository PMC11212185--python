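"""Readers and writers for KRI specifications, subject extracts and reports.

File conventions: CSV is comma-separated UTF-8 with a mandatory header row
and "." decimals; all times are months from trial start (enrollment) or
from the subject's own first dose (events, censoring), serialised with
4-decimal precision.  Reports carry provenance comment lines (``#``) with
the tool version and a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .assessment import SiteAssessment, assessments_to_frame
from .boundaries import (
    BoundarySet,
    ConfigurationError,
    KRIWeights,
    PriorSpec,
    RiskLevelSpec,
)

log = logging.getLogger("rbmon")


class DataError(ValueError):
    """Subject-level input could not be parsed."""


# ---------------------------------------------------------------------------
# KRI specification files (YAML / JSON)
# ---------------------------------------------------------------------------

_KRI_KEYS = {"kri_id", "family", "levels", "reference_time_months", "direction",
             "weight", "prior_masses"}


def read_kri_specs(path: str | Path):
    """Load a KRI specification file.

    Returns ``(specs, priors, weights)``: the per-KRI level specs, a shared
    :class:`PriorSpec` (or None for non-informative), and per-KRI weights.
    Unknown keys are rejected so typos fail loudly.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "kris" not in data:
        raise ConfigurationError("spec file must contain a top-level 'kris' list")
    unknown_top = set(data) - {"kris", "prior_masses"}
    if unknown_top:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown_top)}")
    specs, weights = [], {}
    for entry in data["kris"]:
        unknown = set(entry) - _KRI_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown keys in KRI entry {entry.get('kri_id', '?')!r}: {sorted(unknown)}"
            )
        levels = entry["levels"]
        spec = RiskLevelSpec(
            kri_id=str(entry["kri_id"]),
            family=entry["family"],
            levels=tuple(tuple(lv) if isinstance(lv, list) else lv for lv in levels),
            reference_time=entry.get("reference_time_months"),
            direction=entry.get("direction", "higher_is_riskier"),
            weight=float(entry.get("weight", 1.0)),
        )
        specs.append(spec)
        weights[spec.kri_id] = spec.weight
    priors = PriorSpec(data["prior_masses"]) if "prior_masses" in data else None
    return specs, priors, KRIWeights(weights)


def write_kri_specs(path: str | Path, specs: Sequence[RiskLevelSpec],
                    priors: PriorSpec | None = None) -> None:
    data = {
        "kris": [
            {
                "kri_id": s.kri_id,
                "family": s.family,
                "levels": [list(lv) if isinstance(lv, tuple) else lv for lv in s.levels],
                **({"reference_time_months": s.reference_time}
                   if s.reference_time is not None else {}),
                "direction": s.direction,
                "weight": s.weight,
            }
            for s in specs
        ]
    }
    if priors is not None:
        data["prior_masses"] = list(priors.masses)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Subject-level extracts
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = ("site_id", "kri_id", "enrollment_month", "event_month",
                   "value", "censor_month")


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a subject-level monitoring extract.

    One row per subject x KRI with columns ``site_id, kri_id,
    enrollment_month, event_month, value, censor_month``; ``event_month``
    may hold a semicolon-separated list for recurrent events and is empty
    when no event occurred.  Malformed rows are logged and skipped; a file
    with no parseable rows raises :class:`DataError`.
    """
    raw = pd.read_csv(path, comment="#", dtype=str)
    missing = set(SUBJECT_COLUMNS[:2]) | {"enrollment_month", "censor_month"}
    missing -= set(raw.columns)
    if missing:
        raise DataError(f"subject file lacks required columns: {sorted(missing)}")
    rows, skipped = [], 0
    for i, r in raw.iterrows():
        try:
            ev_field = r.get("event_month")
            events = []
            if isinstance(ev_field, str) and ev_field.strip():
                events = [float(x) for x in ev_field.split(";") if x.strip()]
            val_field = r.get("value")
            value = float(val_field) if isinstance(val_field, str) and val_field.strip() else None
            rows.append(
                {
                    "site_id": str(r["site_id"]),
                    "kri_id": str(r["kri_id"]),
                    "enrollment_time": float(r["enrollment_month"]),
                    "censor_time": float(r["censor_month"]),
                    "event_times": sorted(events),
                    "value": value,
                }
            )
        except (TypeError, ValueError):
            skipped += 1
    if skipped:
        log.warning("skipped %d malformed subject rows", skipped)
    if not rows:
        raise DataError("no parseable subject rows")
    return pd.DataFrame(rows)


def write_subjects(path: str | Path, records: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "site_id": records["site_id"],
            "kri_id": records["kri_id"],
            "enrollment_month": records["enrollment_time"].round(4),
            "event_month": [
                ";".join(f"{t:.4f}" for t in ev) for ev in records["event_times"]
            ],
            "value": records["value"],
            "censor_month": records["censor_time"].round(4),
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _provenance(config: dict | None) -> str:
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# rbmon {__version__}\n# config_hash {digest}\n"


def write_boundary_report(
    path: str | Path,
    bsets: Sequence[tuple[str, BoundarySet]],
    config: dict | None = None,
) -> None:
    """Write a boundary report CSV: one row per (KRI set, level pair)."""
    rows = []
    for kri_set, b in bsets:
        masses = b.prior_used.masses
        for g, value in enumerate(b.boundaries, start=1):
            rows.append(
                {
                    "site_id": b.site_id or "",
                    "kri_set": kri_set,
                    "family": b.family,
                    "scale": b.scale,
                    "level_pair": f"{g}/{g + 1}",
                    "boundary": round(value, 6),
                    "prior_ratio": round(masses[g] / masses[g - 1], 6),
                    "n_k": b.n_k if b.n_k is not None else "",
                    "t_k": round(b.t_k, 4) if b.t_k is not None else "",
                }
            )
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        frame.to_csv(fh, index=False)


def write_assessment_report(
    path: str | Path,
    assessments: Sequence[SiteAssessment],
    config: dict | None = None,
) -> None:
    frame = assessments_to_frame(assessments)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        frame.to_csv(fh, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back any report written by this module (skips provenance)."""
    return pd.read_csv(path, comment="#")
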