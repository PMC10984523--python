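"""Configuration loading and scenario construction.

The packaged ``data/default_config.yaml`` holds every default; a user
config file deep-merges on top of it.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .calendars import month_index
from .impact import DelayImpactParams, SurvivalModel
from .natural_history import ParticipationSeries, PopulationParams
from .scenarios import RunConfig, ScenarioSpec
from .timeline import VolumeChangeRecord


def default_config() -> dict:
    path = resources.files("crcburden").joinpath("data/default_config.yaml")
    with resources.as_file(path) as p:
        return yaml.safe_load(Path(p).read_text())


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Merged configuration: packaged defaults overlaid with a user file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def population_params(cfg: Mapping, seed: int | None = None) -> PopulationParams:
    p = dict(cfg["population"])
    if seed is not None:
        p["random_seed"] = seed
    return PopulationParams(**p)


def run_config(cfg: Mapping) -> RunConfig:
    return RunConfig(
        population=population_params(cfg),
        survival=SurvivalModel.exponential_from_5yr(
            cfg["survival_5yr"], horizon_months=cfg.get("survival_horizon_months", 120)
        ),
        impact=DelayImpactParams(**cfg["impact"]),
        horizon_months=cfg["horizon_months"],
        treatment_mix=dict(cfg["treatment_mix"]),
        queue_engine=cfg["queue"]["engine"],
        timestep_weeks=cfg["queue"]["timestep_weeks"],
        queue_discipline=cfg["queue"]["discipline"],
    )


def seeds_from_config(cfg: Mapping, override: Sequence[int] | None = None) -> tuple[int, ...]:
    if override is not None:
        return tuple(int(s) for s in override)
    block = cfg["seeds"]
    return tuple(int(block["base"]) + i for i in range(int(block["count"])))


def participation_from_changes(
    changes: Sequence[Mapping], horizon_months: int, country_label: str = ""
) -> ParticipationSeries:
    """Monthly participation multipliers from relative-change entries."""
    values = np.ones(horizon_months)
    for ch in changes:
        start = month_index(str(ch["period_start"]))
        n = 12 if ch.get("period_kind", "year") == "year" else 1
        values[start : start + n] = 1.0 + float(ch["relative_change"])
    return ParticipationSeries(values, country_label)


def volume_records_from_config(entries: Sequence[Mapping]) -> tuple[VolumeChangeRecord, ...]:
    return tuple(
        VolumeChangeRecord(
            procedure_type=e["procedure_type"],
            period_start=month_index(str(e["period_start"])),
            period_kind=e.get("period_kind", "year"),
            relative_change=float(e["relative_change"]),
        )
        for e in entries
    )


def country_scenarios(
    cfg: Mapping,
    country: str,
    seeds: Sequence[int] | None = None,
    mitigation_factor: float | None = None,
) -> dict[str, ScenarioSpec]:
    """The standard scenario set for one country.

    Returns the comparator, the screening-only run (decomposition
    diagnostic), the full pandemic run without mitigation, and the
    mitigated run.
    """
    if country not in cfg["countries"]:
        raise ValueError(f"unknown country {country!r}")
    block = cfg["countries"][country]
    horizon = cfg["horizon_months"]
    seeds = seeds_from_config(cfg, seeds)
    participation = participation_from_changes(
        block.get("participation_changes", ()), horizon, country
    )
    records = volume_records_from_config(block.get("volume_records", ()))
    factor = cfg["mitigation"]["factor"] if mitigation_factor is None else mitigation_factor
    mit_start = month_index(str(cfg["mitigation"]["start"]))
    return {
        "no_pandemic": ScenarioSpec(
            name="no_pandemic",
            participation=ParticipationSeries.constant(1.0, horizon, country),
            seeds=seeds,
        ),
        "screening_only": ScenarioSpec(
            name="screening_only", participation=participation, seeds=seeds
        ),
        "pandemic_no_mitigation": ScenarioSpec(
            name="pandemic_no_mitigation",
            participation=participation,
            volume_records=records,
            seeds=seeds,
        ),
        "pandemic_mitigation": ScenarioSpec(
            name="pandemic_mitigation",
            participation=participation,
            volume_records=records,
            mitigation_factor=factor,
            mitigation_start=mit_start,
            seeds=seeds,
        ),
    }


def config_snapshot(cfg: Mapping) -> dict:
    """JSON-serialisable copy of the merged config for run manifests."""
    return yaml.safe_load(yaml.safe_dump(dict(cfg)))
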