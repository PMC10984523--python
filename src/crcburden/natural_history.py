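"""Synthetic colorectal-cancer case streams.

A deliberately simple three-compartment per-person process (precursor
lesion -> preclinical cancer -> clinical presentation, exponential dwell
times) generates monthly diagnosis streams with the qualitative response
surface the downstream analysis needs:

* a screening-participation dip produces fewer screen-detected diagnoses
  during the dip,
* the missed cancers surface later (next round or symptomatically) with a
  worse stage mix,
* missed precursor removals add a small long-term incidence excess.

All latent randomness (onset times, dwell times, stage paths, per-round
attendance and detection uniforms) is drawn from the seed alone, so two
scenarios run on the same seed share one latent population and differ
only through detection — the paired-seed design. Participation identical
to 1.0 therefore reproduces the comparator stream exactly.

Screening is biennial with no catch-up: a missed round is simply missed,
and the person is next screened at their following scheduled round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .impact import STAGES

#: 5-year age bands covering the modelled age range 20-99.
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(20, 100, 5))

SCREENING_AGE_RANGE = (50, 75)  # half-open, years
SCREENING_INTERVAL_MONTHS = 24
MIN_HORIZON_MONTHS = 396  # Jan 2018 .. Dec 2050

DETECTION_MODES = ("screen_detected", "symptomatic")


@dataclass
class PopulationParams:
    """Parameters of the synthetic cohort. Defaults live in the packaged config."""

    cohort_size: int
    age_distribution: Mapping[str, float]
    precursor_incidence_rate: float  # per person-year, before age multipliers
    precursor_to_preclinical_rate: float  # per precursor-year
    preclinical_sojourn_mean: float  # years
    annual_upstage_rate: float  # per undiagnosed-cancer-year
    stage_distribution_at_onset: Sequence[float]
    screening_sensitivity_preclinical: float
    screening_sensitivity_precursor: float
    participation_baseline: float
    other_cause_mortality: Mapping[str, float]  # per person-year, by age band
    random_seed: int = 0
    age_incidence_multipliers: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        rates = (
            self.precursor_incidence_rate,
            self.precursor_to_preclinical_rate,
            self.preclinical_sojourn_mean,
        )
        if not all(np.isfinite(r) and r > 0 for r in rates):
            raise ValueError("all rates must be finite and > 0")
        probs = (
            self.annual_upstage_rate,
            self.screening_sensitivity_preclinical,
            self.screening_sensitivity_precursor,
            self.participation_baseline,
        )
        if not all(np.isfinite(p) and 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be finite and in [0, 1]")
        sd = np.asarray(self.stage_distribution_at_onset, dtype=float)
        if sd.shape != (4,) or np.any(sd < 0) or abs(sd.sum() - 1.0) > 1e-12:
            raise ValueError("stage_distribution_at_onset must be a 4-simplex summing to 1")
        missing = set(AGE_BANDS) - set(self.age_distribution)
        if missing:
            raise ValueError(f"age_distribution missing bands {sorted(missing)}")
        missing = set(AGE_BANDS) - set(self.other_cause_mortality)
        if missing:
            raise ValueError(f"other_cause_mortality missing bands {sorted(missing)}")

    def age_multiplier(self, band: str) -> float:
        if self.age_incidence_multipliers is None:
            return 1.0
        return float(self.age_incidence_multipliers.get(band, 1.0))


@dataclass
class ParticipationSeries:
    """Relative screening-participation multiplier per calendar month (1.0 = status quo)."""

    values: np.ndarray
    country_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("participation multipliers must be finite and >= 0")

    @classmethod
    def constant(cls, value: float, horizon_months: int, country_label: str = "") -> "ParticipationSeries":
        return cls(np.full(horizon_months, value), country_label)

    def padded(self, horizon_months: int) -> np.ndarray:
        """Series padded with 1.0 out to the horizon."""
        if len(self.values) > horizon_months:
            raise ValueError(
                f"participation series ({len(self.values)} months) exceeds the "
                f"horizon ({horizon_months} months)"
            )
        out = np.ones(horizon_months)
        out[: len(self.values)] = self.values
        return out


@dataclass
class CaseRecord:
    """One simulated cancer diagnosis."""

    case_id: int
    age_group: str
    stage_at_diagnosis: str
    detection_mode: str
    onset_month: int
    diagnosis_month: int
    diagnostic_delay_weeks: float = 0.0
    treatment_delay_weeks: float = 0.0
    death_month: int | None = None

    def __post_init__(self) -> None:
        if self.detection_mode not in DETECTION_MODES:
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")
        if self.stage_at_diagnosis not in STAGES:
            raise ValueError(f"unknown stage {self.stage_at_diagnosis!r}")
        if self.diagnosis_month < self.onset_month:
            raise ValueError("diagnosis_month must be >= onset_month")
        if self.diagnostic_delay_weeks < 0 or self.treatment_delay_weeks < 0:
            raise ValueError("delays must be >= 0")
        if self.death_month is not None and self.death_month < self.diagnosis_month:
            raise ValueError("death_month must be >= diagnosis_month")


def _band_index(age_years: np.ndarray) -> np.ndarray:
    idx = ((age_years - 20) // 5).astype(int)
    return np.clip(idx, 0, len(AGE_BANDS) - 1)


def generate_case_stream(
    params: PopulationParams,
    participation: ParticipationSeries,
    horizon_months: int,
) -> list[CaseRecord]:
    """Simulate one seeded cohort and return its diagnosed cases.

    Identical ``(params, participation, seed)`` give a byte-identical
    stream. Cases are sorted by diagnosis month, then case id.
    """
    if horizon_months < MIN_HORIZON_MONTHS:
        raise ValueError(
            f"horizon must cover at least {MIN_HORIZON_MONTHS} months (2018-2050)"
        )
    part = participation.padded(horizon_months)

    rng = np.random.default_rng(params.random_seed)
    n = params.cohort_size
    bands = list(AGE_BANDS)
    weights = np.array([params.age_distribution[b] for b in bands], dtype=float)
    weights = weights / weights.sum()

    # --- latent population: independent of the participation series -----
    band_idx = rng.choice(len(bands), size=n, p=weights)
    age0_months = (20 + 5 * band_idx) * 12 + rng.integers(0, 60, size=n)
    age_mult = np.array([params.age_multiplier(b) for b in bands])[band_idx]
    onset_rate_monthly = params.precursor_incidence_rate * age_mult / 12.0
    t_precursor = rng.exponential(1.0 / onset_rate_monthly)
    dwell_precursor = rng.exponential(12.0 / params.precursor_to_preclinical_rate, size=n)
    sojourn = rng.exponential(params.preclinical_sojourn_mean * 12.0, size=n)
    mort = np.array([params.other_cause_mortality[b] for b in bands])[band_idx]
    t_death = rng.exponential(12.0 / np.maximum(mort, 1e-12))
    stage0 = rng.choice(4, size=n, p=np.asarray(params.stage_distribution_at_onset, dtype=float))
    if params.annual_upstage_rate > 0:
        rho = -np.log1p(-min(params.annual_upstage_rate, 1 - 1e-12)) / 12.0
        upstage_gaps = np.cumsum(rng.exponential(1.0 / rho, size=(n, 3)), axis=1)
    else:
        upstage_gaps = np.full((n, 3), np.inf)
    screen_offset = rng.integers(0, SCREENING_INTERVAL_MONTHS, size=n)
    n_rounds = horizon_months // SCREENING_INTERVAL_MONTHS + 1
    u_attend = rng.random(size=(n, n_rounds))
    u_detect = rng.random(size=(n, n_rounds))

    t_preclinical = t_precursor + dwell_precursor
    t_clinical = t_preclinical + sojourn

    # --- detection: the only place participation enters -----------------
    detected_month = np.full(n, -1, dtype=int)  # screen-detection month
    removed = np.zeros(n, dtype=bool)  # precursor excised at screen
    lo_m, hi_m = SCREENING_AGE_RANGE[0] * 12, SCREENING_AGE_RANGE[1] * 12
    for r in range(n_rounds):
        m = screen_offset + SCREENING_INTERVAL_MONTHS * r
        age_m = age0_months + m
        live = (
            (m < horizon_months)
            & (m < t_death)
            & (m < t_clinical)
            & (detected_month < 0)
            & ~removed
            & (age_m >= lo_m)
            & (age_m < hi_m)
        )
        if not live.any():
            continue
        p_attend = params.participation_baseline * part[np.clip(m, 0, horizon_months - 1)]
        attend = live & (u_attend[:, r] < p_attend)
        in_preclinical = attend & (t_preclinical <= m) & (m < t_clinical)
        hit = in_preclinical & (u_detect[:, r] < params.screening_sensitivity_preclinical)
        detected_month[hit] = m[hit]
        in_precursor = attend & (t_precursor <= m) & (m < t_preclinical)
        removed |= in_precursor & (u_detect[:, r] < params.screening_sensitivity_precursor)

    screen_detected = detected_month >= 0
    symptomatic = (
        ~screen_detected
        & ~removed
        & (t_clinical < horizon_months)
        & (t_clinical < t_death)
    )
    diag_time = np.where(screen_detected, detected_month.astype(float), t_clinical)
    is_case = screen_detected | symptomatic

    # stage at diagnosis: advances while undiagnosed since preclinical onset
    tau = diag_time - t_preclinical
    n_adv = (upstage_gaps <= tau[:, None]).sum(axis=1)
    stage_idx = np.minimum(stage0 + n_adv, 3)

    idx = np.flatnonzero(is_case)
    diag_month = np.floor(diag_time[idx]).astype(int)
    onset_month = np.minimum(np.floor(t_preclinical[idx]).astype(int), diag_month)
    order = np.lexsort((idx, diag_month))
    cases = []
    band_at_diag = _band_index((age0_months[idx] + diag_month) // 12)
    for k in order:
        i = idx[k]
        cases.append(
            CaseRecord(
                case_id=int(i),
                age_group=bands[band_at_diag[k]],
                stage_at_diagnosis=STAGES[stage_idx[i]],
                detection_mode="screen_detected" if screen_detected[i] else "symptomatic",
                onset_month=int(onset_month[k]),
                diagnosis_month=int(diag_month[k]),
            )
        )
    return cases


def split_counterfactual_arrivals(
    cases: Sequence[CaseRecord],
    horizon_months: int,
    treatment_mix: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Monthly procedure arrivals implied by a case stream.

    Every case contributes one diagnostic arrival at its counterfactual
    diagnosis month, plus one treatment arrival per modality assigned by
    independent Bernoulli draws from ``treatment_mix``.

    Returns ``(arrivals, assignments)`` where ``arrivals`` maps procedure
    type to a monthly count array and ``assignments`` maps each modality
    to a boolean array aligned with ``cases``.
    """
    if len(cases) == 0:
        raise ValueError("case stream is empty")
    if treatment_mix is None:
        treatment_mix = {"surgery": 0.7, "chemotherapy": 0.4, "radiotherapy": 0.2}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    diag_months = np.array([c.diagnosis_month for c in cases])
    arrivals = {"diagnosis": np.bincount(diag_months, minlength=horizon_months).astype(float)}
    assignments = {}
    for modality in sorted(treatment_mix):
        p = treatment_mix[modality]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"treatment-mix probability for {modality} must be in [0, 1]")
        take = rng.random(len(cases)) < p
        assignments[modality] = take
        arrivals[modality] = np.bincount(
            diag_months[take], minlength=horizon_months
        ).astype(float)
    return arrivals, assignments


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(c) for c in cases])
    return df.rename(columns={"stage_at_diagnosis": "stage"})


def write_cases(cases: Sequence[CaseRecord], path) -> None:
    cases_to_frame(cases).to_csv(path, index=False)


def read_cases(path) -> list[CaseRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        death = None if pd.isna(row.death_month) else int(row.death_month)
        out.append(
            CaseRecord(
                case_id=int(row.case_id),
                age_group=row.age_group,
                stage_at_diagnosis=row.stage,
                detection_mode=row.detection_mode,
                onset_month=int(row.onset_month),
                diagnosis_month=int(row.diagnosis_month),
                diagnostic_delay_weeks=float(row.diagnostic_delay_weeks),
                treatment_delay_weeks=float(row.treatment_delay_weeks),
                death_month=death,
            )
        )
    return out
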