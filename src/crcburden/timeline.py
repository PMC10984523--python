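"""Capacity-disruption timelines.

Converts observed relative changes in procedure volumes into per-timestep
capacity series for the queue engines: yearly records are expanded to
months, monthly records override yearly ones, a mitigation uplift applies
from its start month onward, and monthly volumes are divided equally
across sub-monthly timesteps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calendars import month_index, month_label

PROCEDURE_TYPES = (
    "screening",
    "diagnosis",
    "diagnostic_procedure",
    "surgery",
    "chemotherapy",
    "radiotherapy",
)

#: Ratio of the relative change in diagnoses to the relative change in
#: diagnostic (colonoscopy) procedures, estimated from regions where both
#: were observed.  Applied only on the diagnostic-procedure pathway.
PROCEDURE_TO_DIAGNOSIS_SCALING = 0.504

# Sub-monthly resampling convention: a month is treated as 4 weeks.
_STEPS_PER_MONTH = {1: 4, 2: 2, 4: 1}


@dataclass(frozen=True)
class VolumeChangeRecord:
    """One observed relative change in procedure volume.

    ``period_start`` is a 0-based month index; yearly records start in
    January and cover 12 months.
    """

    procedure_type: str
    period_start: int
    period_kind: str  # "month" | "year"
    relative_change: float

    def __post_init__(self) -> None:
        if self.procedure_type not in PROCEDURE_TYPES:
            raise ValueError(f"unknown procedure_type {self.procedure_type!r}")
        if self.period_kind not in ("month", "year"):
            raise ValueError(f"period_kind must be 'month' or 'year', got {self.period_kind!r}")
        if not np.isfinite(self.relative_change) or self.relative_change < -1.0:
            raise ValueError(f"relative_change must be finite and >= -1, got {self.relative_change}")

    @property
    def months(self) -> range:
        n = 12 if self.period_kind == "year" else 1
        return range(self.period_start, self.period_start + n)


@dataclass
class CapacitySeries:
    """Per-timestep capacity for one procedure type.

    ``capacity[t] = baseline[t] * multipliers[t]`` at the requested
    timestep; monthly baseline volume is divided equally across the
    timesteps of the month.
    """

    procedure_type: str
    multipliers: np.ndarray
    baseline: np.ndarray
    timestep_weeks: int
    capacity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.multipliers.shape != self.baseline.shape:
            raise ValueError("multipliers and baseline must have equal length")
        if np.any(self.multipliers < 0):
            raise ValueError("capacity multipliers must be >= 0")
        if np.any(self.baseline < 0):
            raise ValueError("baseline volumes must be >= 0")
        self.capacity = self.multipliers * self.baseline

    def __len__(self) -> int:
        return len(self.capacity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "procedure_type": self.procedure_type,
                "timestep_index": np.arange(len(self)),
                "capacity": self.capacity,
            }
        )


def steps_per_month(timestep_weeks: int) -> int:
    try:
        return _STEPS_PER_MONTH[timestep_weeks]
    except KeyError:
        raise ValueError(f"timestep_weeks must be one of {sorted(_STEPS_PER_MONTH)}") from None


def monthly_multipliers(
    records: Iterable[VolumeChangeRecord],
    horizon_months: int,
    mitigation_factor: float = 0.0,
    mitigation_start_month: int | None = None,
) -> np.ndarray:
    """Expand volume-change records into a monthly multiplier series.

    Monthly records take precedence over yearly records covering the same
    month; contradictory records of equal granularity are rejected.
    Months not covered by any record get multiplier 1, or
    ``1 + mitigation_factor`` from the mitigation start onward.
    """
    mult = np.ones(horizon_months)
    if mitigation_start_month is not None and mitigation_factor != 0.0:
        mult[mitigation_start_month:] = 1.0 + mitigation_factor

    seen: dict[int, tuple[str, float]] = {}
    for rec in records:
        for m in rec.months:
            if m < 0 or m >= horizon_months:
                raise ValueError(
                    f"record for {rec.procedure_type} covers month {month_label(max(m, 0))} "
                    f"outside the horizon of {horizon_months} months"
                )
            if m in seen:
                kind, value = seen[m]
                if kind == rec.period_kind:
                    if value != rec.relative_change:
                        raise ValueError(
                            f"contradictory {kind} records for {month_label(m)}: "
                            f"{value} vs {rec.relative_change}"
                        )
                    continue
                if rec.period_kind == "year":
                    continue  # existing monthly record wins
            seen[m] = (rec.period_kind, rec.relative_change)
            mult[m] = 1.0 + rec.relative_change
    if np.any(mult < 0):
        raise ValueError("records imply negative capacity")
    return mult


def resample_monthly(values: np.ndarray, timestep_weeks: int, kind: str) -> np.ndarray:
    """Resample a monthly series to a sub-monthly timestep.

    ``kind='volume'`` divides each month's value equally across its
    timesteps; ``kind='multiplier'`` repeats the monthly value.
    """
    k = steps_per_month(timestep_weeks)
    values = np.asarray(values, dtype=float)
    out = np.repeat(values, k)
    if kind == "volume":
        out = out / k
    elif kind != "multiplier":
        raise ValueError("kind must be 'volume' or 'multiplier'")
    return out


def build_capacity_series(
    records: Sequence[VolumeChangeRecord],
    baseline_monthly: np.ndarray,
    timestep_weeks: int = 2,
    mitigation_factor: float = 0.0,
    mitigation_start_month: int | None = None,
    procedure_type: str = "diagnosis",
) -> CapacitySeries:
    """Build the capacity series for one procedure type.

    ``baseline_monthly`` is the counterfactual monthly arrival/throughput
    volume; the undisrupted queue is exactly in balance against it.
    """
    baseline_monthly = np.asarray(baseline_monthly, dtype=float)
    horizon = len(baseline_monthly)
    relevant = [r for r in records if r.procedure_type == procedure_type]
    mult = monthly_multipliers(relevant, horizon, mitigation_factor, mitigation_start_month)
    return CapacitySeries(
        procedure_type=procedure_type,
        multipliers=resample_monthly(mult, timestep_weeks, "multiplier"),
        baseline=resample_monthly(baseline_monthly, timestep_weeks, "volume"),
        timestep_weeks=timestep_weeks,
    )


def procedures_to_diagnoses(
    procedure_change: float, scaling: float = PROCEDURE_TO_DIAGNOSIS_SCALING
) -> float:
    """Scale a relative change in diagnostic procedures to a change in diagnoses.

    Sign-preserving magnitude scaling.
    """
    if not 0.0 <= scaling <= 1.0:
        raise ValueError(f"scaling must be in [0, 1], got {scaling}")
    if procedure_change < -1.0:
        raise ValueError("procedure_change must be >= -1")
    return scaling * procedure_change


def net_yearly_change(multipliers: np.ndarray, baseline_monthly: np.ndarray) -> float:
    """Net relative change over a year of monthly multipliers.

    Volume-weighted mean of the monthly multipliers minus 1, i.e. the
    yearly total including month-by-month increases and decreases.
    """
    multipliers = np.asarray(multipliers, dtype=float)
    baseline_monthly = np.asarray(baseline_monthly, dtype=float)
    total = baseline_monthly.sum()
    if total <= 0:
        raise ValueError("baseline volume must be positive")
    return float((multipliers * baseline_monthly).sum() / total - 1.0)


def read_volume_records(path) -> list[VolumeChangeRecord]:
    """Read VolumeChangeRecord rows from CSV.

    Columns: procedure_type, period_start (YYYY-MM), period_kind, relative_change.
    """
    df = pd.read_csv(path)
    return [
        VolumeChangeRecord(
            procedure_type=row.procedure_type,
            period_start=month_index(str(row.period_start)),
            period_kind=row.period_kind,
            relative_change=float(row.relative_change),
        )
        for row in df.itertuples()
    ]


def write_capacity_series(series: CapacitySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
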