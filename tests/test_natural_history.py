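import dataclasses

import numpy as np
import pytest

from crcburden.calendars import year_window
from crcburden.natural_history import (
    AGE_BANDS,
    CaseRecord,
    ParticipationSeries,
    PopulationParams,
    cases_to_frame,
    generate_case_stream,
    read_cases,
    split_counterfactual_arrivals,
    write_cases,
)

H = 396


def dip_participation(multiplier=0.6, years=(2020,)):
    values = np.ones(H)
    for y in years:
        lo, hi = year_window(y, y)
        values[lo:hi] = multiplier
    return ParticipationSeries(values)


class TestParams:
    def test_bad_stage_simplex_rejected(self, small_params):
        with pytest.raises(ValueError, match="simplex"):
            dataclasses.replace(small_params, stage_distribution_at_onset=[0.5, 0.5, 0.5, 0.5])

    def test_nonfinite_rate_rejected(self, small_params):
        with pytest.raises(ValueError):
            dataclasses.replace(small_params, precursor_incidence_rate=float("nan"))

    def test_probability_out_of_range_rejected(self, small_params):
        with pytest.raises(ValueError):
            dataclasses.replace(small_params, participation_baseline=1.5)


class TestCaseRecord:
    def test_diagnosis_before_onset_rejected(self):
        with pytest.raises(ValueError):
            CaseRecord(0, "60-64", "I", "symptomatic", onset_month=10, diagnosis_month=5)

    def test_death_before_diagnosis_rejected(self):
        with pytest.raises(ValueError):
            CaseRecord(0, "60-64", "I", "symptomatic", 0, 10, death_month=5)


class TestGenerateCaseStream:
    def test_unit_participation_is_comparator(self, small_params, unit_participation):
        a = generate_case_stream(small_params, unit_participation, H)
        b = generate_case_stream(small_params, ParticipationSeries.constant(1.0, H), H)
        assert a == b

    def test_determinism(self, small_params, unit_participation):
        a = generate_case_stream(small_params, unit_participation, H)
        b = generate_case_stream(small_params, unit_participation, H)
        assert a == b

    def test_seed_changes_stream(self, small_params, unit_participation):
        a = generate_case_stream(small_params, unit_participation, H)
        b = generate_case_stream(
            dataclasses.replace(small_params, random_seed=1), unit_participation, H
        )
        assert a != b

    def test_zero_participation_no_screen_detected(self, small_params):
        cases = generate_case_stream(small_params, ParticipationSeries.constant(0.0, H), H)
        assert cases
        assert all(c.detection_mode == "symptomatic" for c in cases)

    def test_conservation_and_invariants(self, small_params, unit_participation):
        cases = generate_case_stream(small_params, unit_participation, H)
        ids = [c.case_id for c in cases]
        assert len(ids) == len(set(ids))  # one diagnosis per person
        for c in cases:
            assert c.detection_mode in ("screen_detected", "symptomatic")
            assert 0 <= c.onset_month <= c.diagnosis_month < H
            assert c.age_group in AGE_BANDS

    def test_horizon_too_short_rejected(self, small_params, unit_participation):
        with pytest.raises(ValueError, match="horizon"):
            generate_case_stream(small_params, unit_participation, 100)

    def test_participation_longer_than_horizon_rejected(self, small_params):
        with pytest.raises(ValueError, match="exceeds"):
            ParticipationSeries.constant(1.0, H + 1).padded(H)

    def test_screen_detection_within_eligible_ages(self, small_params, unit_participation):
        cases = generate_case_stream(small_params, unit_participation, H)
        for c in cases:
            if c.detection_mode == "screen_detected":
                assert 50 <= int(c.age_group.split("-")[0]) <= 74

    def test_symptomatic_stage_mix_worse_than_screen_detected(self, small_params):
        # pooled over seeds: upstaging during the sojourn makes symptomatic
        # presentations later-stage than screen detections
        order = {"I": 1, "II": 2, "III": 3, "IV": 4}
        scr, sym = [], []
        for seed in range(20):
            params = dataclasses.replace(small_params, random_seed=seed)
            for c in generate_case_stream(params, ParticipationSeries.constant(1.0, H), H):
                (scr if c.detection_mode == "screen_detected" else sym).append(
                    order[c.stage_at_diagnosis]
                )
        assert np.mean(sym) > np.mean(scr)

    def test_dip_reduces_screen_detected_and_raises_longterm_incidence(self, small_params):
        # paired seeds: 40% participation drop in 2020 only
        y2020 = year_window(2020, 2020)
        w2030 = year_window(2020, 2030)
        sd_drop, cum_excess = [], []
        for seed in range(60):
            params = dataclasses.replace(small_params, random_seed=seed)
            base = generate_case_stream(params, ParticipationSeries.constant(1.0, H), H)
            dip = generate_case_stream(params, dip_participation(0.6), H)

            def count(cases, window, mode=None):
                return sum(
                    1
                    for c in cases
                    if window[0] <= c.diagnosis_month < window[1]
                    and (mode is None or c.detection_mode == mode)
                )

            sd_drop.append(
                count(base, y2020, "screen_detected") - count(dip, y2020, "screen_detected")
            )
            cum_excess.append(count(dip, w2030) - count(base, w2030))
        assert np.mean(sd_drop) > 0
        assert np.mean(cum_excess) > 0

    def test_deeper_dip_monotone(self, small_params):
        y2020 = year_window(2020, 2020)
        means = []
        for mult in (1.0, 0.6, 0.2):
            counts = []
            for seed in range(30):
                params = dataclasses.replace(small_params, random_seed=seed)
                cases = generate_case_stream(params, dip_participation(mult), H)
                counts.append(
                    sum(
                        1
                        for c in cases
                        if y2020[0] <= c.diagnosis_month < y2020[1]
                        and c.detection_mode == "screen_detected"
                    )
                )
            means.append(np.mean(counts))
        assert means[0] > means[1] > means[2]


class TestSplitCounterfactualArrivals:
    def _cases(self, months):
        return [
            CaseRecord(i, "60-64", "II", "symptomatic", 0, m) for i, m in enumerate(months)
        ]

    def test_single_month_concentration(self):
        arrivals, _ = split_counterfactual_arrivals(self._cases([7] * 10), 24)
        assert arrivals["diagnosis"][7] == 10
        assert arrivals["diagnosis"].sum() == 10

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_counterfactual_arrivals([], 24)

    def test_conservation(self):
        cases = self._cases([1, 2, 2, 5, 9])
        arrivals, _ = split_counterfactual_arrivals(cases, 24)
        assert arrivals["diagnosis"].sum() == len(cases)

    def test_treatment_mix_law_of_large_numbers(self):
        cases = self._cases(list(range(100)) )
        mix = {"surgery": 0.7, "chemotherapy": 0.4, "radiotherapy": 0.2}
        totals = {m: [] for m in mix}
        for seed in range(200):
            arrivals, _ = split_counterfactual_arrivals(cases, 120, mix, seed=seed)
            for m in mix:
                totals[m].append(arrivals[m].sum())
        for m, p in mix.items():
            # mean of Binomial(100, p) over 200 seeds; SE ~ 0.32
            assert np.mean(totals[m]) == pytest.approx(100 * p, abs=1.5)

    def test_assignments_align_with_arrivals(self):
        cases = self._cases([3, 3, 4])
        arrivals, assignments = split_counterfactual_arrivals(cases, 12, seed=1)
        for m, take in assignments.items():
            assert arrivals[m].sum() == take.sum()


class TestCaseIO:
    def test_roundtrip(self, tmp_path, small_params, unit_participation):
        cases = generate_case_stream(small_params, unit_participation, H)[:50]
        path = tmp_path / "cases.csv"
        write_cases(cases, path)
        assert read_cases(path) == cases

    def test_frame_columns(self, small_params, unit_participation):
        cases = generate_case_stream(small_params, unit_participation, H)[:5]
        df = cases_to_frame(cases)
        assert {
            "case_id",
            "age_group",
            "stage",
            "detection_mode",
            "onset_month",
            "diagnosis_month",
            "diagnostic_delay_weeks",
            "treatment_delay_weeks",
            "death_month",
        } <= set(df.columns)
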