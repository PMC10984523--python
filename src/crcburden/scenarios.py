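"""End-to-end scenario runs and excess-outcome accounting.

A scenario couples a screening-participation series with capacity-change
records and an optional post-2022 mitigation uplift. Each replicate seed
runs the full pipeline

    case stream -> capacity series -> backlog queues -> delay impact

against a paired comparator stream generated from the *same* seed with
participation 1.0, so scenario-minus-comparator differences isolate the
disruption. Baseline queue capacity equals the comparator's per-step
arrival counts: the undisrupted queue is exactly in balance and a
zero-magnitude shock reproduces the comparator bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import backlog, impact, timeline
from .calendars import year_window
from .impact import DelayImpactParams, STAGES, SurvivalModel
from .natural_history import (
    AGE_BANDS,
    CaseRecord,
    ParticipationSeries,
    PopulationParams,
    generate_case_stream,
    split_counterfactual_arrivals,
)
from .reporting import OutcomeTable
from .timeline import CapacitySeries, VolumeChangeRecord, procedures_to_diagnoses, steps_per_month

MITIGATION_EARLIEST_MONTH = year_window(2022, 2022)[0]  # Jan 2022

TREATMENT_MODALITIES = ("chemotherapy", "radiotherapy", "surgery")

#: Reporting windows (half-open month-index intervals).
REPORTING_WINDOWS: dict[str, tuple[int, int]] = {
    "2020-2021": year_window(2020, 2021),
    "2020-2025": year_window(2020, 2025),
    "2020-2030": year_window(2020, 2030),
    "2020-2050": year_window(2020, 2050),
}


@dataclass
class ScenarioSpec:
    name: str
    participation: ParticipationSeries
    volume_records: tuple[VolumeChangeRecord, ...] = ()
    mitigation_factor: float = 0.0
    mitigation_start: int | None = None
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.volume_records = tuple(self.volume_records)
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.mitigation_factor != 0.0:
            if self.mitigation_start is None:
                raise ValueError("mitigation_factor set without mitigation_start")
            if self.mitigation_start < MITIGATION_EARLIEST_MONTH:
                raise ValueError("mitigation cannot start before January 2022")
        if self.name == "no_pandemic":
            if np.any(self.participation.values != 1.0):
                raise ValueError("no_pandemic scenario must have unit participation")
            if self.volume_records or self.mitigation_factor:
                raise ValueError("no_pandemic scenario must have no shocks or mitigation")

    @property
    def is_comparator(self) -> bool:
        return (
            np.all(self.participation.values == 1.0)
            and not self.volume_records
            and self.mitigation_factor == 0.0
        )


@dataclass
class RunConfig:
    """Everything a scenario run needs besides the scenario itself."""

    population: PopulationParams
    survival: SurvivalModel
    impact: DelayImpactParams = field(default_factory=DelayImpactParams)
    horizon_months: int = 396
    treatment_mix: Mapping[str, float] = field(
        default_factory=lambda: {"surgery": 0.7, "chemotherapy": 0.4, "radiotherapy": 0.2}
    )
    queue_engine: str = "agent"  # or "aggregate"
    timestep_weeks: int = 2
    queue_discipline: str = "random"

    def __post_init__(self) -> None:
        if self.queue_engine not in ("agent", "aggregate"):
            raise ValueError("queue_engine must be 'agent' or 'aggregate'")


def _case_arrival_steps(cases: Sequence[CaseRecord], k: int) -> np.ndarray:
    """Deterministic within-month step assignment (round-robin by rank)."""
    months = np.array([c.diagnosis_month for c in cases])
    steps = np.empty(len(cases), dtype=int)
    rank: dict[int, int] = {}
    for i, m in enumerate(months):
        r = rank.get(m, 0)
        steps[i] = m * k + (r % k)
        rank[m] = r + 1
    return steps


def _queue_records(spec: ScenarioSpec, procedure: str) -> list[VolumeChangeRecord]:
    """Capacity records feeding the queue for one procedure type.

    Diagnostic-procedure records are converted into diagnosis-capacity
    records with the procedures-to-diagnoses magnitude scaling.
    """
    out = []
    for rec in spec.volume_records:
        if rec.procedure_type == procedure:
            out.append(rec)
        elif procedure == "diagnosis" and rec.procedure_type == "diagnostic_procedure":
            out.append(
                VolumeChangeRecord(
                    procedure_type="diagnosis",
                    period_start=rec.period_start,
                    period_kind=rec.period_kind,
                    relative_change=procedures_to_diagnoses(rec.relative_change),
                )
            )
    return out


def _run_queue(
    arrivals_per_step: np.ndarray,
    capacity: CapacitySeries,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict[int, list[float]]:
    """Run the configured engine; return waits (weeks) grouped by arrival step."""
    if cfg.queue_engine == "agent":
        dist = backlog.simulate_agent_queue(
            arrivals_per_step, capacity, rng, discipline=cfg.queue_discipline
        )
        waits_by_step: dict[int, list[float]] = {}
        for step, wait in zip(dist.arrival_step, dist.waits_weeks):
            waits_by_step.setdefault(int(step), []).append(float(wait))
    else:
        dist, _ = backlog.run_aggregate_queue(arrivals_per_step, capacity)
        waits_by_step = {}
        for step, wait, w in zip(dist.arrival_step, dist.waits_weeks, dist.weights):
            waits_by_step[int(step)] = [float(wait)] * int(round(w))
    return waits_by_step


def _assign_waits(steps: np.ndarray, waits_by_step: Mapping[int, list[float]]) -> np.ndarray:
    """Assign queue waits back to cases, in case order within each step."""
    out = np.zeros(len(steps))
    cursor: dict[int, int] = {}
    for i, s in enumerate(steps):
        s = int(s)
        j = cursor.get(s, 0)
        out[i] = waits_by_step[s][j]
        cursor[s] = j + 1
    return out


def _deaths_by_band(
    cases: Sequence[CaseRecord],
    survival: SurvivalModel,
    params: DelayImpactParams,
    horizon_months: int,
    delayed: bool,
) -> np.ndarray:
    """(horizon, n_bands) expected monthly CRC deaths."""
    out = np.zeros((horizon_months, len(AGE_BANDS)))
    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}
    max_fu = survival.horizon_months
    base_inc = {s: -np.diff(survival.curves[s]) for s in STAGES}
    cache: dict[tuple[str, float], np.ndarray] = {}
    for case in cases:
        if delayed:
            m = impact.delay_hazard_multiplier(
                impact.effective_hr_delay_weeks(case, params), params
            )
            inc = np.zeros(max_fu)
            for stage, w in impact._stage_distribution(case, params).items():
                key = (stage, m)
                if key not in cache:
                    cache[key] = -np.diff(survival.curves[stage] ** m)
                inc += w * cache[key]
        else:
            inc = base_inc[case.stage_at_diagnosis]
        start = case.diagnosis_month
        end = min(horizon_months, start + max_fu)
        out[start:end, band_idx[case.age_group]] += inc[: end - start]
    return out


def expected_person_years(params: PopulationParams, horizon_months: int) -> np.ndarray:
    """(n_years, n_bands) expected person-years, aging the start-age mixture.

    Start ages are uniform within each 5-year band; other-cause mortality
    is ignored for exposure (a surrogate-level approximation). Ages at or
    above the top band's lower bound accumulate in the top band.
    """
    bands = list(AGE_BANDS)
    weights = np.array([params.age_distribution[b] for b in bands], dtype=float)
    weights = weights / weights.sum()
    lowers = np.array([int(b.split("-")[0]) for b in bands], dtype=float)
    n_years = horizon_months // 12
    py = np.zeros((n_years, len(bands)))
    for m in range(n_years * 12):
        shift = m / 12.0
        for j, w in enumerate(weights):
            lo, hi = lowers[j] + shift, lowers[j] + 5.0 + shift
            for b in range(len(bands)):
                b_lo = lowers[b]
                b_hi = np.inf if b == len(bands) - 1 else b_lo + 5.0
                overlap = max(0.0, min(hi, b_hi) - max(lo, b_lo))
                if overlap > 0:
                    py[m // 12, b] += params.cohort_size * w * overlap / 5.0 / 12.0
    return py


def run_scenario(spec: ScenarioSpec, cfg: RunConfig) -> OutcomeTable:
    """Run a scenario over its replicate seeds and return the mean outcome table."""
    tables = []
    py = expected_person_years(cfg.population, cfg.horizon_months)
    for seed in spec.seeds:
        try:
            tables.append(_run_single(spec, cfg, seed, py))
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"scenario {spec.name!r} failed at seed {seed}: {exc}") from exc
    return OutcomeTable.mean(tables)


def _run_single(spec: ScenarioSpec, cfg: RunConfig, seed: int, py: np.ndarray) -> OutcomeTable:
    H = cfg.horizon_months
    params = replace(cfg.population, random_seed=seed)
    cases = generate_case_stream(params, spec.participation, H)
    if spec.is_comparator:
        comp_cases = cases
    else:
        comp_cases = generate_case_stream(params, ParticipationSeries.constant(1.0, H), H)

    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    diagnoses = np.zeros((H, len(AGE_BANDS)))
    by_stage = np.zeros((H, len(STAGES)))

    if not cases:
        return OutcomeTable(
            diagnoses=diagnoses,
            deaths=np.zeros_like(diagnoses),
            diagnoses_by_stage=by_stage,
            person_years=py,
            seeds=(seed,),
        )

    k = steps_per_month(cfg.timestep_weeks)
    _, assignments = split_counterfactual_arrivals(
        cases, H, cfg.treatment_mix, seed=np.random.default_rng([seed, 7])
    )
    _, comp_assignments = split_counterfactual_arrivals(
        comp_cases, H, cfg.treatment_mix, seed=np.random.default_rng([seed, 7])
    )

    n_steps = H * k
    steps = _case_arrival_steps(cases, k)
    comp_steps = _case_arrival_steps(comp_cases, k)

    def capacity_for(procedure: str, baseline_steps: np.ndarray) -> CapacitySeries:
        baseline = np.bincount(baseline_steps, minlength=n_steps).astype(float)
        records = _queue_records(spec, procedure)
        mult_monthly = timeline.monthly_multipliers(
            records, H, spec.mitigation_factor, spec.mitigation_start
        )
        return CapacitySeries(
            procedure_type=procedure,
            multipliers=np.repeat(mult_monthly, k),
            baseline=baseline,
            timestep_weeks=cfg.timestep_weeks,
        )

    # diagnostic queue
    diag_arrivals = np.bincount(steps, minlength=n_steps).astype(float)
    cap = capacity_for("diagnosis", comp_steps)
    waits = _run_queue(diag_arrivals, cap, cfg, np.random.default_rng([seed, 11]))
    diag_delay_weeks = _assign_waits(steps, waits)

    # treatment queues, arrivals pushed back by the diagnostic delay
    treat_delay_weeks = np.zeros(len(cases))
    delay_steps = np.rint(diag_delay_weeks / cfg.timestep_weeks).astype(int)
    for qi, modality in enumerate(TREATMENT_MODALITIES):
        take = assignments[modality]
        if not take.any():
            continue
        t_steps = np.minimum(steps[take] + delay_steps[take], n_steps - 1)
        arrivals = np.bincount(t_steps, minlength=n_steps).astype(float)
        comp_take = comp_assignments[modality]
        cap = capacity_for(modality, comp_steps[comp_take])
        waits = _run_queue(arrivals, cap, cfg, np.random.default_rng([seed, 13 + qi]))
        w = _assign_waits(t_steps, waits)
        treat_delay_weeks[take] = np.maximum(treat_delay_weeks[take], w)

    for case, dd, td in zip(cases, diag_delay_weeks, treat_delay_weeks):
        case.diagnostic_delay_weeks = float(dd)
        case.treatment_delay_weeks = float(td)
        actual_month = min(case.diagnosis_month + int(round(dd / 4.0)), H - 1)
        diagnoses[actual_month, band_idx[case.age_group]] += 1
        by_stage[actual_month, stage_idx[case.stage_at_diagnosis]] += 1

    deaths = _deaths_by_band(cases, cfg.survival, cfg.impact, H, delayed=True)
    return OutcomeTable(
        diagnoses=diagnoses,
        deaths=deaths,
        diagnoses_by_stage=by_stage,
        person_years=py,
        seeds=(seed,),
    )


@dataclass
class ExcessTable:
    """Windowed excess outcomes vs the comparator, with the screening /
    diagnosis-treatment decomposition."""

    windows: Mapping[str, tuple[int, int]]
    excess_cases: Mapping[str, float]
    excess_deaths_total: Mapping[str, float]
    excess_deaths_screening: Mapping[str, float]
    excess_deaths_diag_treat: Mapping[str, float]
    relative_change_cases: Mapping[str, float]
    relative_change_deaths: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.windows:
            rows.append(
                {
                    "window": name,
                    "excess_cases": self.excess_cases[name],
                    "excess_deaths_screening_related": self.excess_deaths_screening[name],
                    "excess_deaths_diag_treat_related": self.excess_deaths_diag_treat[name],
                    "excess_deaths_total": self.excess_deaths_total[name],
                    "relative_change_cases": self.relative_change_cases[name],
                    "relative_change_deaths": self.relative_change_deaths[name],
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            name: {
                "excess_cases": self.excess_cases[name],
                "excess_deaths": {
                    "screening_related": self.excess_deaths_screening[name],
                    "diagnoses_treatment_related": self.excess_deaths_diag_treat[name],
                    "total": self.excess_deaths_total[name],
                },
                "relative_change_cases": self.relative_change_cases[name],
                "relative_change_deaths": self.relative_change_deaths[name],
            }
            for name in self.windows
        }


def decompose_excess(
    run_all: OutcomeTable,
    run_screening_only: OutcomeTable,
    comparator: OutcomeTable,
    windows: Mapping[str, tuple[int, int]] | None = None,
) -> ExcessTable:
    """Difference three paired runs into the Table-3 style decomposition.

    screening_related = screening-only - comparator;
    diag/treat related = full - screening-only; the two components sum to
    the total exactly in unrounded floats.
    """
    for other in (run_screening_only, comparator):
        if other.seeds != run_all.seeds:
            raise ValueError("decomposition requires runs on identical seeds")
    windows = dict(REPORTING_WINDOWS if windows is None else windows)
    cases, deaths_total, deaths_scr, deaths_dt = {}, {}, {}, {}
    rel_cases, rel_deaths = {}, {}
    for name, w in windows.items():
        cases[name] = run_all.total("diagnoses", w) - comparator.total("diagnoses", w)
        scr = run_screening_only.total("deaths", w) - comparator.total("deaths", w)
        dt = run_all.total("deaths", w) - run_screening_only.total("deaths", w)
        deaths_scr[name], deaths_dt[name] = scr, dt
        deaths_total[name] = scr + dt
        comp_cases = comparator.total("diagnoses", w)
        comp_deaths = comparator.total("deaths", w)
        rel_cases[name] = cases[name] / comp_cases if comp_cases else float("nan")
        rel_deaths[name] = deaths_total[name] / comp_deaths if comp_deaths else float("nan")
    return ExcessTable(
        windows=windows,
        excess_cases=cases,
        excess_deaths_total=deaths_total,
        excess_deaths_screening=deaths_scr,
        excess_deaths_diag_treat=deaths_dt,
        relative_change_cases=rel_cases,
        relative_change_deaths=rel_deaths,
    )


def mitigation_reduction(no_mitigation_excess: float, mitigation_excess: float) -> float:
    """Relative reduction in excess deaths achieved by mitigation."""
    if no_mitigation_excess <= 0:
        raise ValueError("no-mitigation excess must be > 0")
    return (no_mitigation_excess - mitigation_excess) / no_mitigation_excess


def deaths_averted(no_mitigation_excess: float, mitigation_excess: float) -> float:
    """Absolute excess deaths averted by mitigation over a window."""
    if no_mitigation_excess <= 0:
        raise ValueError("no-mitigation excess must be > 0")
    return no_mitigation_excess - mitigation_excess
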