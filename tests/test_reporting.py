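import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crcburden import config as cfgmod
from crcburden.natural_history import AGE_BANDS
from crcburden.reporting import (
    OutcomeTable,
    StandardPopulation,
    age_standardised_rate,
    map_model_bands_to_standard,
    relative_change_series,
    write_outputs,
)
from crcburden.scenarios import expected_person_years


class TestStandardPopulation:
    def test_segi_loads_and_normalises(self):
        std = StandardPopulation.segi()
        assert len(std.labels) == 18
        assert std.labels[0] == "0-4"
        assert std.labels[-1] == "85+"
        assert std.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(std.weights > 0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            StandardPopulation(labels=("a", "b"), weights=np.array([1.0, 0.0]))

    def test_model_band_mapping_pools_85plus(self):
        out = map_model_bands_to_standard({"85-89": 1.0, "90-94": 2.0, "95-99": 3.0, "50-54": 4.0})
        assert out == {"85+": 6.0, "50-54": 4.0}


class TestAgeStandardisedRate:
    def test_constant_rate_identity(self):
        std = StandardPopulation.segi()
        r = 0.0007
        events = {b: r * 1000.0 for b in std.labels}
        py = {b: 1000.0 for b in std.labels}
        assert age_standardised_rate(events, py, std) == pytest.approx(r * 100_000)

    def test_two_band_hand_arithmetic(self):
        std = StandardPopulation(labels=("a", "b"), weights=np.array([0.25, 0.75]))
        events = {"a": 1.0, "b": 3.0}
        py = {"a": 1000.0, "b": 1000.0}
        # 100000 * (0.25*0.001 + 0.75*0.003) = 250
        assert age_standardised_rate(events, py, std) == pytest.approx(250.0)

    def test_zero_events(self):
        std = StandardPopulation.segi()
        assert age_standardised_rate({}, {b: 10.0 for b in std.labels}, std) == 0.0

    def test_misaligned_band_named(self):
        std = StandardPopulation.segi()
        with pytest.raises(ValueError, match="17-22"):
            age_standardised_rate({"17-22": 1.0}, {"17-22": 10.0}, std)

    def test_events_without_person_years_rejected(self):
        std = StandardPopulation.segi()
        with pytest.raises(ValueError, match="person-years"):
            age_standardised_rate({"50-54": 5.0}, {}, std)

    def test_band_split_invariance(self):
        # splitting a band into two with identical rates leaves the ASR unchanged
        joined = StandardPopulation(labels=("x", "y"), weights=np.array([0.4, 0.6]))
        split = StandardPopulation(labels=("x1", "x2", "y"), weights=np.array([0.2, 0.2, 0.6]))
        asr_joined = age_standardised_rate(
            {"x": 8.0, "y": 9.0}, {"x": 4000.0, "y": 3000.0}, joined
        )
        asr_split = age_standardised_rate(
            {"x1": 4.0, "x2": 4.0, "y": 9.0},
            {"x1": 2000.0, "x2": 2000.0, "y": 3000.0},
            split,
        )
        assert asr_joined == pytest.approx(asr_split, rel=1e-12)

    @given(
        rates=st.lists(st.floats(min_value=0.0, max_value=0.01), min_size=3, max_size=3),
        split_frac=st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_band_split_invariance_property(self, rates, split_frac):
        w = np.array([0.3, 0.3, 0.4])
        joined = StandardPopulation(labels=("a", "b", "c"), weights=w)
        split = StandardPopulation(
            labels=("a1", "a2", "b", "c"),
            weights=np.array([w[0] * split_frac, w[0] * (1 - split_frac), w[1], w[2]]),
        )
        py = 1000.0
        ev = {"a": rates[0] * py, "b": rates[1] * py, "c": rates[2] * py}
        pys = {k: py for k in ev}
        ev2 = {
            "a1": rates[0] * py * split_frac,
            "a2": rates[0] * py * (1 - split_frac),
            "b": ev["b"],
            "c": ev["c"],
        }
        pys2 = {"a1": py * split_frac, "a2": py * (1 - split_frac), "b": py, "c": py}
        assert age_standardised_rate(ev, pys, joined) == pytest.approx(
            age_standardised_rate(ev2, pys2, split), rel=1e-9
        )


def toy_outcome_table(horizon=24, diag_level=2.0, death_level=0.5, seeds=(0,)):
    n_bands = len(AGE_BANDS)
    diagnoses = np.full((horizon, n_bands), diag_level)
    deaths = np.full((horizon, n_bands), death_level)
    by_stage = np.zeros((horizon, 4))
    py = np.full((horizon // 12, n_bands), 1000.0)
    return OutcomeTable(diagnoses, deaths, by_stage, py, seeds=seeds)


class TestOutcomeTable:
    def test_window_totals(self):
        table = toy_outcome_table()
        assert table.total("diagnoses", (0, 12)) == pytest.approx(12 * len(AGE_BANDS) * 2.0)

    def test_annual_asr_constant_rate(self):
        std = StandardPopulation.segi()
        table = toy_outcome_table()
        asr = table.annual_asr("diagnoses", std)
        # every covered band rate = 24/1000 per year; Segi bands below 20
        # have no model population and contribute zero
        covered = sum(
            w for label, w in zip(std.labels, std.weights) if label == "85+" or int(label.split("-")[0]) >= 20
        )
        assert np.allclose(asr, 24.0 / 1000.0 * 100_000 * covered)

    def test_mean_pools_seeds(self):
        a = toy_outcome_table(diag_level=2.0, seeds=(1,))
        b = toy_outcome_table(diag_level=4.0, seeds=(2,))
        m = OutcomeTable.mean([a, b])
        assert np.allclose(m.diagnoses, 3.0)
        assert m.seeds == (1, 2)


class TestRelativeChangeSeries:
    def test_identity_zero(self):
        std = StandardPopulation.segi()
        table = toy_outcome_table()
        df = relative_change_series(table, table, std)
        assert np.allclose(df["asir_relative_change"], 0.0)
        assert np.allclose(df["asmr_relative_change"], 0.0)

    def test_direct_arithmetic(self):
        std = StandardPopulation.segi()
        comparator = toy_outcome_table(diag_level=2.0)
        scenario = toy_outcome_table(diag_level=1.9)
        df = relative_change_series(scenario, comparator, std)
        assert np.allclose(df["asir_relative_change"], -0.05)

    def test_zero_comparator_flagged_nan(self):
        std = StandardPopulation.segi()
        comparator = toy_outcome_table(diag_level=0.0, death_level=0.0)
        scenario = toy_outcome_table(diag_level=1.0)
        df = relative_change_series(scenario, comparator, std)
        assert df["asir_relative_change"].isna().all()


class TestPersonYears:
    def test_total_exposure_conserved(self, small_params):
        py = expected_person_years(small_params, 24)
        # every cohort member contributes one person-year per year
        assert np.allclose(py.sum(axis=1), small_params.cohort_size, rtol=1e-9)

    def test_aging_shifts_bands(self, small_params):
        py = expected_person_years(small_params, 396)
        first, last = py[0], py[-1]
        young = slice(0, 4)
        assert last[young].sum() < first[young].sum()


class TestWriteOutputs:
    def test_roundtrip_and_manifest(self, tmp_path):
        table = toy_outcome_table()
        written = write_outputs(
            tmp_path,
            {"no_pandemic": table},
            excess=pd.DataFrame({"window": ["2020-2021"], "excess_deaths_total": [1.5]}),
            excess_json={"2020-2021": {"total": 1.5}},
            config_snapshot={"alpha": 1},
            seeds=(3, 4, 5),
        )
        frame = pd.read_csv(written["outcomes_no_pandemic"])
        back = frame.pivot(index="month", columns="age_band", values="diagnoses")
        assert np.allclose(np.sort(back.to_numpy(), axis=None),
                           np.sort(table.diagnoses, axis=None))
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seeds"] == [3, 4, 5]
        assert manifest["config"] == {"alpha": 1}
        assert json.loads((tmp_path / "excess_table.json").read_text())[
            "2020-2021"
        ]["total"] == 1.5


class TestConfig:
    def test_defaults_load(self, default_cfg):
        assert default_cfg["impact"]["hr_per_4_weeks"] == 1.06
        assert default_cfg["mitigation"]["factor"] == 0.05

    def test_deep_merge_override(self, tmp_path):
        user = tmp_path / "user.yaml"
        user.write_text("population:\n  cohort_size: 123\n")
        cfg = cfgmod.load_config(user)
        assert cfg["population"]["cohort_size"] == 123
        assert cfg["population"]["participation_baseline"] == 0.60

    def test_country_scenarios_structure(self, default_cfg):
        specs = cfgmod.country_scenarios(default_cfg, "canada", seeds=[1, 2])
        assert set(specs) == {
            "no_pandemic",
            "screening_only",
            "pandemic_no_mitigation",
            "pandemic_mitigation",
        }
        assert specs["no_pandemic"].is_comparator
        assert specs["pandemic_mitigation"].mitigation_factor == 0.05
        # Canada: -40% screening through 2020
        part = specs["screening_only"].participation.values
        assert np.allclose(part[24:36], 0.60)
        assert np.allclose(part[36:48], 1.0)
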