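"""Candidate-event detection, filters, component evaluation, and the grid."""

import numpy as np
import pandas as pd
import pytest

from pneumolink.algorithm_engine import (
    algorithm_by_id,
    apply_algorithm,
    enumerate_algorithms,
    evaluate_components,
    find_index_events,
    flag_hospital_acquired,
    require_same_day_entry,
)

from conftest import make_dataset, make_windows, obs_row, patient_row, rx_row, spell

WINDOWS = make_windows([("P1", "2015-01-01", "2019-12-31")])


def events_from(observations, bundle, windows=WINDOWS, **kwargs):
    ds = make_dataset([patient_row("P1")], observations)
    return find_index_events(ds.observations, bundle.pneumonia, windows, **kwargs)


class TestEnumeration:
    def test_nineteen_algorithms(self):
        specs = enumerate_algorithms()
        assert len(specs) == 19
        assert [s.id for s in specs] == list(range(1, 20))

    def test_first_is_code_only(self):
        assert enumerate_algorithms()[0].required_columns() == []

    def test_last_requires_full_combination(self):
        last = enumerate_algorithms()[-1]
        assert last.requires_cxr and last.requires_symptoms
        assert last.antibiotics_mode == "any_duration"
        assert last.requires_culture_positive

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm id"):
            algorithm_by_id(20)


class TestDeduplication:
    def test_codes_within_gap_collapse(self, bundle):
        ev = events_from(
            [obs_row("P1", "PNEU001", "2017-03-01"), obs_row("P1", "PNEU002", "2017-03-11")],
            bundle,
        )
        assert len(ev) == 1
        assert ev["index_date"].iloc[0] == pd.Timestamp("2017-03-01")

    def test_codes_beyond_gap_split(self, bundle):
        ev = events_from(
            [obs_row("P1", "PNEU001", "2017-03-01"), obs_row("P1", "PNEU001", "2017-03-21")],
            bundle,
        )
        assert len(ev) == 2

    def test_event_outside_window_dropped(self, bundle):
        ev = events_from([obs_row("P1", "PNEU001", "2014-12-31")], bundle)
        assert ev.empty

    def test_order_independent_and_idempotent(self, bundle):
        rng = np.random.default_rng(7)
        days = sorted(int(x) for x in rng.integers(0, 1500, size=40))
        obs = [
            obs_row(
                "P1",
                "PNEU001",
                (pd.Timestamp("2015-01-01") + pd.Timedelta(days=day)).strftime("%Y-%m-%d"),
            )
            for day in days
        ]
        base = events_from(obs, bundle)
        shuffled = [obs[i] for i in rng.permutation(len(obs))]
        again = events_from(shuffled, bundle)
        pd.testing.assert_frame_equal(base, again)
        # feeding the index codes back through produces the same events
        reduced = [
            obs_row("P1", "PNEU001", str(ts)[:10]) for ts in base["index_date"]
        ]
        pd.testing.assert_frame_equal(events_from(reduced, bundle), base)


class TestSameDayEntry:
    @pytest.mark.parametrize(
        "entry,kept",
        [("2017-03-01", True), ("2017-03-02", False), ("2017-02-27", False)],
    )
    def test_prospective_coding_required(self, bundle, entry, kept):
        ev = events_from([obs_row("P1", "PNEU001", "2017-03-01", entry)], bundle)
        filtered = require_same_day_entry(ev)
        assert len(filtered) == (1 if kept else 0)


class TestHospitalAcquired:
    def flag(self, bundle, index_date, spells):
        ev = events_from([obs_row("P1", "PNEU001", index_date)], bundle)
        return bool(flag_hospital_acquired(ev, spells)["hospital_acquired"].iloc[0])

    def test_index_during_prior_admission_flagged(self, bundle):
        s = spell("S1", "P1", "2017-02-20", "2017-03-05", [(1, "2017-02-20", ["J440"])])
        assert self.flag(bundle, "2017-03-01", [s])

    def test_ten_days_post_discharge_flagged(self, bundle):
        s = spell("S1", "P1", "2017-02-01", "2017-02-19", [(1, "2017-02-01", ["J440"])])
        assert self.flag(bundle, "2017-03-01", [s])

    def test_thirty_days_post_discharge_not_flagged(self, bundle):
        s = spell("S1", "P1", "2017-01-01", "2017-01-30", [(1, "2017-01-01", ["J440"])])
        assert not self.flag(bundle, "2017-03-01", [s])

    def test_same_day_admission_is_community_onset(self, bundle):
        # an admission on the index date is the event's consequence
        s = spell("S1", "P1", "2017-03-01", "2017-03-09", [(1, "2017-03-01", ["J181"])])
        assert not self.flag(bundle, "2017-03-01", [s])


class TestComponents:
    def evaluate(self, bundle, observations, prescriptions=()):
        ds = make_dataset([patient_row("P1")], observations, list(prescriptions))
        ev = find_index_events(ds.observations, bundle.pneumonia, WINDOWS)
        return evaluate_components(ev, ds.observations, ds.prescriptions, bundle)

    def test_two_distinct_symptom_categories_required(self, bundle):
        two = self.evaluate(
            bundle,
            [
                obs_row("P1", "PNEU001", "2017-03-03"),
                obs_row("P1", "SYMP101", "2017-03-01"),  # new cough
                obs_row("P1", "SYMP401", "2017-03-04"),  # fever
            ],
        )
        one = self.evaluate(
            bundle,
            [
                obs_row("P1", "PNEU001", "2017-03-03"),
                obs_row("P1", "SYMP101", "2017-03-01"),
                obs_row("P1", "SYMP102", "2017-03-04"),  # same category twice
            ],
        )
        assert bool(two["symptoms"].iloc[0])
        assert not bool(one["symptoms"].iloc[0])

    def test_component_window_boundaries(self, bundle):
        inside = self.evaluate(
            bundle,
            [obs_row("P1", "PNEU001", "2017-03-08"), obs_row("P1", "CXR001", "2017-03-01")],
        )
        outside = self.evaluate(
            bundle,
            [obs_row("P1", "PNEU001", "2017-03-09"), obs_row("P1", "CXR001", "2017-03-01")],
        )
        assert bool(inside["cxr"].iloc[0])
        assert not bool(outside["cxr"].iloc[0])

    @pytest.mark.parametrize(
        "duration,any_flag,range_flag",
        [(4, True, False), (5, True, True), (14, True, True), (15, True, False), (None, True, False)],
    )
    def test_antibiotic_duration_boundaries(self, bundle, duration, any_flag, range_flag):
        ev = self.evaluate(
            bundle,
            [obs_row("P1", "PNEU001", "2017-03-03")],
            [rx_row("P1", "ABX001", "2017-03-05", duration)],
        )
        assert bool(ev["abx_any"].iloc[0]) is any_flag
        assert bool(ev["abx_5_14"].iloc[0]) is range_flag

    def test_culture_codes_detected(self, bundle):
        ev = self.evaluate(
            bundle,
            [
                obs_row("P1", "PNEU001", "2017-03-03"),
                obs_row("P1", "CULT001", "2017-03-02"),
                obs_row("P1", "CPOS002", "2017-03-06"),
            ],
        )
        assert bool(ev["culture_sent"].iloc[0]) and bool(ev["culture_positive"].iloc[0])


class TestApplyAlgorithm:
    @pytest.fixture
    def random_events(self):
        rng = np.random.default_rng(11)
        n = 50
        frame = pd.DataFrame(
            {
                "event_id": np.arange(n),
                "patient_id": [f"P{i}" for i in range(n)],
                "index_date": pd.Timestamp("2017-01-01") + pd.to_timedelta(rng.integers(0, 900, n), "D"),
                "entry_date": pd.Timestamp("2017-01-01"),
                "same_day_entry": True,
            }
        )
        for col in ("symptoms", "cxr", "culture_sent", "culture_positive", "abx_any", "abx_5_14"):
            frame[col] = rng.random(n) < 0.4
        return frame

    def test_code_only_is_identity(self, random_events):
        out = apply_algorithm(algorithm_by_id(1), random_events)
        pd.testing.assert_frame_equal(out, random_events.reset_index(drop=True))

    def test_missing_component_flag_rejected(self, random_events):
        with pytest.raises(ValueError, match="cxr"):
            apply_algorithm(algorithm_by_id(3), random_events.drop(columns=["cxr"]))

    def test_required_flag_false_excludes_event(self, random_events):
        out = apply_algorithm(algorithm_by_id(3), random_events)
        assert out["cxr"].all()
        assert set(out["event_id"]) == set(
            random_events.loc[random_events["cxr"], "event_id"]
        )

    def test_every_algorithm_subset_of_code_only(self, random_events):
        base = set(apply_algorithm(algorithm_by_id(1), random_events)["event_id"])
        for spec in enumerate_algorithms():
            qualifying = set(apply_algorithm(spec, random_events)["event_id"])
            assert qualifying <= base

    def test_nested_requirements_give_nested_event_sets(self, random_events):
        specs = enumerate_algorithms()
        sets = {s.id: set(apply_algorithm(s, random_events)["event_id"]) for s in specs}
        reqs = {s.id: set(s.required_columns()) for s in specs}
        compared = 0
        for a in specs:
            for b in specs:
                if reqs[a.id] < reqs[b.id]:
                    assert sets[b.id] <= sets[a.id], (a.id, b.id)
                    compared += 1
        assert compared > 30  # the grid genuinely nests
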