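"""Right-censored time-to-event records and Kaplan-Meier estimation.

The cohort container is a list of :class:`SurvivalRecord`; each record
carries overall-survival (OS) and progression-free-survival (PFS) follow-up
in months plus binary marker calls and free-form categorical covariates.
Kaplan-Meier estimation is delegated to lifelines; the resulting
:class:`KMCurve` keeps only the distinct event times (censored-only times
reduce the risk set but add no step), which is the fitting surface the
plateau model operates on.

Conventions: time unit is months (fractional allowed) measured from
diagnosis; at tied times events precede censorings (the standard KM
convention); a PFS event is relapse, progression, or death from any cause,
whichever occurs first, so ``pfs_time <= time`` always.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import math

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import EmptyCohortError, ValidationError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "km_estimate",
    "follow_up_summary",
    "records_to_frame",
    "frame_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
]

_ENDPOINTS = ("OS", "PFS")


@dataclass
class SurvivalRecord:
    """One patient's follow-up, event status, marker calls and covariates."""

    sample_id: str
    time: float                 # OS follow-up, months > 0
    os_event: bool              # death observed
    pfs_time: float             # PFS follow-up, months > 0
    pfs_event: bool             # progression/relapse/death observed
    satb1_positive: bool = False
    p16_positive: bool = False
    covariates: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, t in (("time", self.time), ("pfs_time", self.pfs_time)):
            if not (math.isfinite(t) and t > 0):
                raise ValidationError(
                    f"{name} must be strictly positive and finite, got {t!r} "
                    f"(sample {self.sample_id!r})"
                )
        if self.pfs_time > self.time + 1e-12:
            raise ValidationError(
                f"pfs_time ({self.pfs_time}) exceeds os time ({self.time}) "
                f"for sample {self.sample_id!r}"
            )
        if self.os_event and not self.pfs_event:
            raise ValidationError(
                f"death implies a PFS event (sample {self.sample_id!r})"
            )


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray       # ordered distinct event times, months
    survival: np.ndarray    # S(t_i), non-increasing, in [0, 1]
    at_risk: np.ndarray     # n_i just before t_i
    n_events: np.ndarray    # d_i at t_i
    n_total: int = 0        # cohort size

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        self.n_events = np.asarray(self.n_events, dtype=int)
        n = len(self.times)
        if not (len(self.survival) == len(self.at_risk) == len(self.n_events) == n):
            raise ValidationError("KMCurve fields must have equal length")

    def __len__(self) -> int:
        return len(self.times)


def _endpoint_columns(records: Sequence[SurvivalRecord], endpoint: str) -> Tuple[np.ndarray, np.ndarray]:
    ep = str(endpoint).upper()
    if ep not in _ENDPOINTS:
        raise ValidationError(f"endpoint must be one of {_ENDPOINTS}, got {endpoint!r}")
    if ep == "OS":
        times = np.array([r.time for r in records], dtype=float)
        events = np.array([r.os_event for r in records], dtype=bool)
    else:
        times = np.array([r.pfs_time for r in records], dtype=float)
        events = np.array([r.pfs_event for r in records], dtype=bool)
    return times, events


def km_estimate(
    records: Sequence[SurvivalRecord],
    endpoint: str = "OS",
    at: str = "events",
) -> KMCurve:
    """Kaplan-Meier product-limit estimate for the chosen endpoint.

    S(t_i) = prod_{j<=i} (1 - d_j/n_j) over the distinct event times t_i.

    ``at="events"`` (default) evaluates the curve at the distinct event
    times only -- censored-only times reduce the risk set but add no step.
    ``at="observed"`` evaluates the same estimate at every distinct
    observed time (events and censorings); this is the staircase a
    regression package sees when the curve is exported for fitting, and it
    retains the information censored follow-up carries about the tail.
    """
    records = list(records)
    if not records:
        raise EmptyCohortError("km_estimate needs at least one record")
    if at not in ("events", "observed"):
        raise ValidationError(f"at must be 'events' or 'observed', got {at!r}")
    times, events = _endpoint_columns(records, endpoint)

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table  # indexed by observed times, includes t=0 row
    if at == "events":
        rows = table[table["observed"] > 0]
    else:
        rows = table[(table["observed"] > 0) | (table["censored"] > 0)]
    out_times = rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(out_times).to_numpy(dtype=float)
    return KMCurve(
        times=out_times,
        survival=surv,
        at_risk=rows["at_risk"].to_numpy(dtype=int),
        n_events=rows["observed"].to_numpy(dtype=int),
        n_total=len(records),
    )


def follow_up_summary(records: Sequence[SurvivalRecord]) -> Dict[str, float]:
    """Median and range of observed OS follow-up times, all subjects."""
    records = list(records)
    if not records:
        raise EmptyCohortError("follow_up_summary needs at least one record")
    t = np.array([r.time for r in records], dtype=float)
    return {"median": float(np.median(t)), "min": float(t.min()), "max": float(t.max())}


# ---------------------------------------------------------------------------
# CSV round-trip (survival_core dialect)

_CORE_COLUMNS = [
    "sample_id",
    "os_time_months",
    "os_event",
    "pfs_time_months",
    "pfs_event",
    "satb1_positive",
    "p16_positive",
]


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "os_time_months": r.time,
            "os_event": int(r.os_event),
            "pfs_time_months": r.pfs_time,
            "pfs_event": int(r.pfs_event),
            "satb1_positive": int(r.satb1_positive),
            "p16_positive": int(r.p16_positive),
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> List[SurvivalRecord]:
    missing = [c for c in _CORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
    covariate_cols = [c for c in frame.columns if c not in _CORE_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        records.append(
            SurvivalRecord(
                sample_id=str(row["sample_id"]),
                time=float(row["os_time_months"]),
                os_event=bool(int(row["os_event"])),
                pfs_time=float(row["pfs_time_months"]),
                pfs_event=bool(int(row["pfs_event"])),
                satb1_positive=bool(int(row["satb1_positive"])),
                p16_positive=bool(int(row["p16_positive"])),
                covariates={c: row[c] for c in covariate_cols},
            )
        )
    return records


def read_cohort_csv(path) -> List[SurvivalRecord]:
    return frame_to_records(pd.read_csv(path))


def write_cohort_csv(records: Iterable[SurvivalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
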