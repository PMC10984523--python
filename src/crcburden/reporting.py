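"""Age-standardised rates, outcome tables, and output writers.

Rates are standardised to the Segi world standard population (packaged as
a data table, 18 five-year bands with 85+ aggregation). Model age bands
20-99 map onto the standard bands, with 85-89/90-94/95-99 pooled into
85+. ASRs are annual.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calendars import month_label, ORIGIN_YEAR
from .impact import STAGES
from .natural_history import AGE_BANDS


@dataclass
class StandardPopulation:
    """Age-band labels and normalised weights of a standard population."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("standard-population weights must be > 0")
        self.weights = self.weights / self.weights.sum()
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights failed to normalise")

    @classmethod
    def segi(cls) -> "StandardPopulation":
        path = resources.files("crcburden").joinpath("data/segi_world_standard.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
        return cls(labels=tuple(df["age_band"]), weights=df["weight"].to_numpy())


def map_model_bands_to_standard(values: Mapping[str, float]) -> dict[str, float]:
    """Aggregate model age bands (20-99) onto Segi bands (85+ pooled)."""
    out: dict[str, float] = {}
    for band, v in values.items():
        lo = int(band.split("-")[0])
        key = "85+" if lo >= 85 else band
        out[key] = out.get(key, 0.0) + v
    return out


def age_standardised_rate(
    events: Mapping[str, float],
    person_years: Mapping[str, float],
    standard: StandardPopulation,
) -> float:
    """ASR per 100,000: sum of weighted age-specific rates.

    Bands absent from ``events`` contribute rate 0; every band with
    events must align with a standard band and have person-years.
    """
    wmap = dict(zip(standard.labels, standard.weights))
    asr = 0.0
    for band, n in events.items():
        if band not in wmap:
            raise ValueError(f"age band {band!r} does not align with the standard population")
        py = person_years.get(band, 0.0)
        if n > 0 and py <= 0:
            raise ValueError(f"age band {band!r} has events but no person-years")
        if py > 0:
            asr += wmap[band] * (n / py) * 100_000.0
    return asr


@dataclass
class OutcomeTable:
    """Monthly diagnoses and expected deaths by age band, plus person-years.

    ``diagnoses`` and ``deaths`` are ``(horizon_months, n_bands)`` arrays;
    ``diagnoses_by_stage`` is ``(horizon_months, 4)``; ``person_years`` is
    ``(n_years, n_bands)``. All values may be seed-averaged means.
    """

    diagnoses: np.ndarray
    deaths: np.ndarray
    diagnoses_by_stage: np.ndarray
    person_years: np.ndarray
    age_bands: tuple[str, ...] = AGE_BANDS
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.diagnoses = np.asarray(self.diagnoses, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.diagnoses_by_stage = np.asarray(self.diagnoses_by_stage, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.diagnoses.shape != self.deaths.shape:
            raise ValueError("diagnoses and deaths must share shape")
        if np.any(self.diagnoses < -1e-9) or np.any(self.deaths < -1e-9):
            raise ValueError("counts must be >= 0")

    @property
    def horizon_months(self) -> int:
        return self.diagnoses.shape[0]

    @property
    def n_years(self) -> int:
        return self.person_years.shape[0]

    def total(self, kind: str, window: tuple[int, int]) -> float:
        """Total diagnoses or deaths over a half-open month window."""
        arr = self.diagnoses if kind == "diagnoses" else self.deaths
        lo, hi = window
        return float(arr[lo:hi].sum())

    def annual_events_by_band(self, kind: str) -> np.ndarray:
        """(n_years, n_bands) annual event counts."""
        arr = self.diagnoses if kind == "diagnoses" else self.deaths
        n_years = arr.shape[0] // 12
        return arr[: n_years * 12].reshape(n_years, 12, -1).sum(axis=1)

    def annual_asr(self, kind: str, standard: StandardPopulation) -> np.ndarray:
        """Annual ASR series (per 100,000) for diagnoses or deaths."""
        events = self.annual_events_by_band(kind)
        n_years = min(events.shape[0], self.person_years.shape[0])
        out = np.empty(n_years)
        for y in range(n_years):
            ev = map_model_bands_to_standard(dict(zip(self.age_bands, events[y])))
            py = map_model_bands_to_standard(dict(zip(self.age_bands, self.person_years[y])))
            out[y] = age_standardised_rate(ev, py, standard)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in range(self.horizon_months):
            for b, band in enumerate(self.age_bands):
                rows.append(
                    {
                        "month": month_label(m),
                        "age_band": band,
                        "diagnoses": self.diagnoses[m, b],
                        "deaths": self.deaths[m, b],
                    }
                )
        return pd.DataFrame(rows)

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.diagnoses_by_stage,
            columns=[f"stage_{s}" for s in STAGES],
        ).assign(month=[month_label(m) for m in range(self.horizon_months)])

    @classmethod
    def mean(cls, tables: Sequence["OutcomeTable"]) -> "OutcomeTable":
        if not tables:
            raise ValueError("no tables to average")
        return cls(
            diagnoses=np.mean([t.diagnoses for t in tables], axis=0),
            deaths=np.mean([t.deaths for t in tables], axis=0),
            diagnoses_by_stage=np.mean([t.diagnoses_by_stage for t in tables], axis=0),
            person_years=np.mean([t.person_years for t in tables], axis=0),
            age_bands=tables[0].age_bands,
            seeds=tuple(s for t in tables for s in t.seeds),
        )


def relative_change_series(
    scenario: OutcomeTable,
    comparator: OutcomeTable,
    standard: StandardPopulation,
) -> pd.DataFrame:
    """Per-year relative changes in ASIR and ASMR vs the comparator.

    Years with zero comparator ASR are flagged NaN rather than silently
    divided.
    """
    if scenario.horizon_months != comparator.horizon_months:
        raise ValueError("scenario and comparator horizons differ")
    rows = {}
    for kind, name in (("diagnoses", "asir_relative_change"), ("deaths", "asmr_relative_change")):
        s = scenario.annual_asr(kind, standard)
        c = comparator.annual_asr(kind, standard)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(c > 0, (s - c) / np.where(c > 0, c, 1.0), np.nan)
        rows[name] = rel
    n_years = len(rows["asir_relative_change"])
    return pd.DataFrame({"year": ORIGIN_YEAR + np.arange(n_years), **rows})


def write_outputs(
    out_dir,
    tables: Mapping[str, OutcomeTable],
    excess: "pd.DataFrame | None" = None,
    excess_json: dict | None = None,
    config_snapshot: dict | None = None,
    seeds: Sequence[int] = (),
    plots: bool = False,
) -> dict[str, str]:
    """Write outcome tables, excess tables, and a run manifest.

    Returns a map of artefact name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name, table in tables.items():
        path = out_dir / f"outcomes_{name}.csv"
        table.to_frame().to_csv(path, index=False, float_format="%.17g")
        written[f"outcomes_{name}"] = str(path)
    if excess is not None:
        path = out_dir / "excess_table.csv"
        excess.to_csv(path, index=False, float_format="%.17g")
        written["excess_table"] = str(path)
    if excess_json is not None:
        path = out_dir / "excess_table.json"
        path.write_text(json.dumps(excess_json, indent=2))
        written["excess_table_json"] = str(path)
    manifest = {
        "seeds": list(map(int, seeds)),
        "config": config_snapshot or {},
        "wall_time_unix": time.time(),
        "package": "crcburden",
    }
    try:  # best effort: version metadata is absent in editable dev trees
        from importlib.metadata import version

        manifest["version"] = version("crcburden")
    except Exception:
        manifest["version"] = "unknown"
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = str(path)
    if plots and tables:
        written.update(_plot_cumulative(out_dir, tables))
    return written


def _plot_cumulative(out_dir: Path, tables: Mapping[str, OutcomeTable]) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    comparator = tables.get("no_pandemic")
    for name, table in tables.items():
        if comparator is None or name == "no_pandemic":
            continue
        months = np.arange(table.horizon_months)
        dd = np.cumsum(table.diagnoses.sum(axis=1) - comparator.diagnoses.sum(axis=1))
        dm = np.cumsum(table.deaths.sum(axis=1) - comparator.deaths.sum(axis=1))
        axes[0].plot(months, dd, label=name)
        axes[1].plot(months, dm, label=name)
    axes[0].set_ylabel("cumulative additional diagnoses")
    axes[1].set_ylabel("cumulative additional deaths")
    axes[1].set_xlabel("months since 2018-01")
    axes[0].legend()
    path = out_dir / "cumulative_excess.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return {"plot_cumulative": str(path)}


def read_outcome_frame(path) -> pd.DataFrame:
    return pd.read_csv(path)
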