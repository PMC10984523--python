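"""Health impact of diagnostic and treatment delays.

Additional waits are converted into excess cancer mortality through a
mortality hazard ratio per 4-week delay (default 1.06), applied under
proportional hazards to stage-specific baseline survival. Diagnostic
delays can also advance the stage at diagnosis (upstaging), with the
probability of advancing one stage compounding the annual upstage rate
over the fractional year of delay.

Double-counting guard: the hazard ratio (and upstaging) is not applied to
diagnostic delays of screen-detected cancers, whose detection shifts are
already captured upstream by the natural-history generator; only their
treatment delays contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")

#: Default 5-year survival by stage used to parameterise exponential
#: baseline curves. Config-overridable placeholders, not registry values.
DEFAULT_SURVIVAL_5YR = {"I": 0.95, "II": 0.85, "III": 0.70, "IV": 0.15}


@dataclass
class SurvivalModel:
    """Stage-specific baseline survival curves on a monthly grid.

    ``curves[stage][t]`` is survival probability at ``t`` months since
    diagnosis, ``t = 0..horizon``; ``S(0) = 1`` and S is non-increasing.
    """

    curves: Mapping[str, np.ndarray]
    form: str = "tabular"

    def __post_init__(self) -> None:
        validated = {}
        for stage, s in self.curves.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage label {stage!r}")
            s = np.asarray(s, dtype=float)
            if s[0] != 1.0:
                raise ValueError(f"stage {stage}: survival at t=0 must be 1")
            if np.any(np.diff(s) > 1e-12):
                raise ValueError(f"stage {stage}: survival must be non-increasing")
            if np.any((s < 0) | (s > 1)):
                raise ValueError(f"stage {stage}: survival must lie in [0, 1]")
            validated[stage] = s
        missing = set(STAGES) - set(validated)
        if missing:
            raise ValueError(f"missing survival curves for stages {sorted(missing)}")
        self.curves = validated

    @property
    def horizon_months(self) -> int:
        return len(next(iter(self.curves.values()))) - 1

    @classmethod
    def exponential_from_5yr(
        cls, survival_5yr: Mapping[str, float] | None = None, horizon_months: int = 120
    ) -> "SurvivalModel":
        """Exponential curves with monthly hazard matching 5-year survival."""
        survival_5yr = dict(DEFAULT_SURVIVAL_5YR if survival_5yr is None else survival_5yr)
        t = np.arange(horizon_months + 1)
        curves = {}
        for stage in STAGES:
            lam = -math.log(survival_5yr[stage]) / 60.0
            curves[stage] = np.exp(-lam * t)
        return cls(curves=curves, form="exponential")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in STAGES:
            for t, s in enumerate(self.curves[stage]):
                rows.append({"stage": stage, "month": t, "survival": s})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalModel":
        curves = {
            stage: grp.sort_values("month")["survival"].to_numpy()
            for stage, grp in df.groupby("stage")
        }
        return cls(curves=curves)


@dataclass
class DelayImpactParams:
    hr_per_4_weeks: float = 1.06
    annual_upstage_rate: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STAGES}
    )
    apply_diagnostic_hr_to_screen_detected: bool = False
    hr_compounding: str = "continuous"  # or "blocks": whole 4-week blocks only

    def __post_init__(self) -> None:
        if not self.hr_per_4_weeks > 0:
            raise ValueError("hr_per_4_weeks must be > 0")
        if isinstance(self.annual_upstage_rate, (int, float)):
            self.annual_upstage_rate = {s: float(self.annual_upstage_rate) for s in STAGES}
        for stage, r in self.annual_upstage_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"annual upstage rate for stage {stage} must be in [0, 1]")
        if self.hr_compounding not in ("continuous", "blocks"):
            raise ValueError("hr_compounding must be 'continuous' or 'blocks'")


def delay_hazard_multiplier(delay_weeks: float, params: DelayImpactParams) -> float:
    """Hazard multiplier for a delay: ``hr ** (delay_weeks / 4)``.

    Continuous compounding by default; 'blocks' mode compounds per whole
    4-week block for sensitivity analyses.
    """
    if delay_weeks < 0:
        raise ValueError("delay must be >= 0")
    exponent = delay_weeks / 4.0
    if params.hr_compounding == "blocks":
        exponent = math.floor(exponent)
    return params.hr_per_4_weeks**exponent


def apply_hazard_to_survival(survival: SurvivalModel, multiplier: float) -> SurvivalModel:
    """Proportional-hazards transform: every curve is raised to ``multiplier``."""
    if not multiplier > 0:
        raise ValueError("hazard multiplier must be > 0")
    return SurvivalModel(
        curves={stage: s**multiplier for stage, s in survival.curves.items()},
        form=survival.form,
    )


def upstage_probability(stage: str, delay_weeks: float, params: DelayImpactParams) -> float:
    """Probability the stage advances one step during a diagnostic delay.

    Compounds the annual rate over the fractional year of delay:
    ``1 - (1 - rate) ** (delay_weeks / 52)``. Stage IV is absorbing.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage label {stage!r}")
    if delay_weeks < 0:
        raise ValueError("delay must be >= 0")
    if stage == "IV":
        return 0.0
    rate = params.annual_upstage_rate[stage]
    if rate >= 1.0:
        return 1.0 if delay_weeks > 0 else 0.0
    return 1.0 - (1.0 - rate) ** (delay_weeks / 52.0)


def apply_upstaging(
    stage: str,
    diagnostic_delay_weeks: float,
    params: DelayImpactParams,
    rng: np.random.Generator | None = None,
):
    """Stage after a diagnostic delay.

    Analytic mode (``rng=None``) returns the {stage: probability}
    distribution; sampling mode draws a stage. Delays advance at most one
    stage; stage IV absorbs.
    """
    p = upstage_probability(stage, diagnostic_delay_weeks, params)
    if p == 0.0:
        dist = {stage: 1.0}
    else:
        nxt = STAGES[STAGES.index(stage) + 1]
        dist = {stage: 1.0 - p, nxt: p}
    if rng is None:
        return dist
    stages = list(dist)
    return stages[rng.choice(len(stages), p=list(dist.values()))]


def _stage_distribution(case, params: DelayImpactParams) -> dict[str, float]:
    """Stage distribution after upstaging for a case's effective diagnostic delay."""
    d = case.diagnostic_delay_weeks
    if case.detection_mode == "screen_detected" and not params.apply_diagnostic_hr_to_screen_detected:
        d = 0.0  # captured upstream; guard against double counting
    return apply_upstaging(case.stage_at_diagnosis, d, params)


def effective_hr_delay_weeks(case, params: DelayImpactParams) -> float:
    """Delay entering the hazard-ratio exponent for one case.

    Treatment delay always counts; diagnostic delay counts only for
    symptomatic cases (unless the double-counting guard is disabled).
    """
    d = case.treatment_delay_weeks
    if case.detection_mode == "symptomatic" or params.apply_diagnostic_hr_to_screen_detected:
        d += case.diagnostic_delay_weeks
    return d


def excess_deaths(
    cases: Iterable,
    survival: SurvivalModel,
    params: DelayImpactParams,
    horizon_months: int,
) -> np.ndarray:
    """Monthly expected excess-death series from per-case delays.

    Per case the contribution in follow-up month t is the difference of
    monthly death increments between the delayed curve (upstaged stage
    mix, hazard-multiplied survival) and the baseline curve for the stage
    at diagnosis; contributions land at calendar month
    ``diagnosis_month + t`` and are truncated at the horizon.
    """
    cases = list(cases)
    max_fu = survival.horizon_months
    if cases:
        max_diag = max(c.diagnosis_month for c in cases)
        if horizon_months < max_diag + 1:
            raise ValueError("horizon shorter than the latest diagnosis month")
    series = np.zeros(horizon_months)
    # cache per (stage, multiplier) the monthly death increments
    base_inc = {s: -np.diff(survival.curves[s]) for s in STAGES}
    inc_cache: dict[tuple[str, float], np.ndarray] = {}
    for case in cases:
        m = delay_hazard_multiplier(effective_hr_delay_weeks(case, params), params)
        stage_dist = _stage_distribution(case, params)
        delayed_inc = np.zeros(max_fu)
        for stage, w in stage_dist.items():
            key = (stage, m)
            if key not in inc_cache:
                inc_cache[key] = -np.diff(survival.curves[stage] ** m)
            delayed_inc += w * inc_cache[key]
        diff = delayed_inc - base_inc[case.stage_at_diagnosis]
        start = case.diagnosis_month
        end = min(horizon_months, start + max_fu)
        series[start:end] += diff[: end - start]
    return series


def expected_deaths_series(
    cases: Iterable,
    survival: SurvivalModel,
    params: DelayImpactParams,
    horizon_months: int,
    delayed: bool = True,
) -> np.ndarray:
    """Monthly expected CRC deaths (absolute, not excess).

    ``delayed=False`` evaluates every case on its baseline stage and
    curve, ignoring delays — the comparator bookkeeping.
    """
    series = np.zeros(horizon_months)
    base_inc = {s: -np.diff(survival.curves[s]) for s in STAGES}
    inc_cache: dict[tuple[str, float], np.ndarray] = {}
    max_fu = survival.horizon_months
    for case in cases:
        if delayed:
            m = delay_hazard_multiplier(effective_hr_delay_weeks(case, params), params)
            stage_dist = _stage_distribution(case, params)
            inc = np.zeros(max_fu)
            for stage, w in stage_dist.items():
                key = (stage, m)
                if key not in inc_cache:
                    inc_cache[key] = -np.diff(survival.curves[stage] ** m)
                inc += w * inc_cache[key]
        else:
            inc = base_inc[case.stage_at_diagnosis]
        start = case.diagnosis_month
        end = min(horizon_months, start + max_fu)
        series[start:end] += inc[: end - start]
    return series
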