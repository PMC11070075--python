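"""Linkage, gold-standard classification, PPV and sensitivity estimation."""

import pandas as pd
import pytest

from pneumolink.algorithm_engine import algorithm_by_id
from pneumolink.codelists import CategoryMap
from pneumolink.validation import (
    breakdown_nonpneumonia,
    build_gold_table,
    check_gp_recording,
    classify_gold,
    compute_ppv,
    compute_sensitivity,
    find_hospital_pneumonia_events,
    link_admissions,
)

from conftest import make_dataset, make_windows, obs_row, patient_row, spell


def simple_events(entries):
    """entries: list of (event_id, patient_id, index_date)."""
    return pd.DataFrame(
        {
            "event_id": [e[0] for e in entries],
            "patient_id": [e[1] for e in entries],
            "index_date": pd.to_datetime([e[2] for e in entries]),
            "entry_date": pd.to_datetime([e[2] for e in entries]),
            "same_day_entry": True,
        }
    )


class TestLinkage:
    def gold(self, spells):
        return build_gold_table(spells)

    def test_day_seven_boundary_links(self):
        s = spell("S1", "P1", "2017-03-08", "2017-03-12", [(1, "2017-03-08", ["J181"])])
        linked = link_admissions(simple_events([(0, "P1", "2017-03-01")]), self.gold([s]))
        assert len(linked) == 1
        assert int(linked["days_to_admission"].iloc[0]) == 7

    def test_day_eight_does_not_link(self):
        s = spell("S1", "P1", "2017-03-09", "2017-03-12", [(1, "2017-03-09", ["J181"])])
        linked = link_admissions(simple_events([(0, "P1", "2017-03-01")]), self.gold([s]))
        assert linked.empty

    def test_same_day_admission_links_at_day_zero(self):
        s = spell("S1", "P1", "2017-03-01", "2017-03-05", [(1, "2017-03-01", ["J181"])])
        linked = link_admissions(simple_events([(0, "P1", "2017-03-01")]), self.gold([s]))
        assert int(linked["days_to_admission"].iloc[0]) == 0

    def test_earliest_admission_wins(self):
        s2 = spell("S2", "P1", "2017-03-03", "2017-03-06", [(1, "2017-03-03", ["J440"])])
        s5 = spell("S5", "P1", "2017-03-06", "2017-03-09", [(1, "2017-03-06", ["J181"])])
        linked = link_admissions(simple_events([(0, "P1", "2017-03-01")]), self.gold([s5, s2]))
        assert linked["spell_id"].iloc[0] == "S2"

    def test_tie_broken_by_spell_id(self):
        sa = spell("SA", "P1", "2017-03-03", "2017-03-06", [(1, "2017-03-03", ["J181"])])
        sb = spell("SB", "P1", "2017-03-03", "2017-03-06", [(1, "2017-03-03", ["J440"])])
        linked = link_admissions(simple_events([(0, "P1", "2017-03-01")]), self.gold([sb, sa]))
        assert linked["spell_id"].iloc[0] == "SA"


class TestGoldClassification:
    def test_primary_position_rule(self):
        s = spell("S1", "P1", "2018-01-01", "2018-01-05", [(1, "2018-01-01", ["J181", "J440"])])
        assert classify_gold(s) == "pneumonia"

    def test_mode_contrast_on_secondary_pneumonia(self):
        s = spell("S1", "P1", "2018-01-01", "2018-01-05", [(1, "2018-01-01", ["J440", "J181"])])
        assert classify_gold(s, mode="primary_last_episode") == "copd"
        assert classify_gold(s, mode="any_position_last_episode") == "pneumonia"

    def test_circulatory_in_both_modes(self):
        s = spell("S1", "P1", "2018-01-01", "2018-01-05", [(1, "2018-01-01", ["I219"])])
        for mode in ("primary_last_episode", "any_position_last_episode"):
            assert classify_gold(s, mode=mode) == "circulatory"

    def test_last_episode_carries_the_gold(self):
        s = spell(
            "S1",
            "P1",
            "2018-01-01",
            "2018-01-09",
            [(1, "2018-01-01", ["J181"]), (2, "2018-01-05", ["J440"])],
        )
        assert classify_gold(s) == "copd"

    def test_unknown_mode_rejected(self):
        s = spell("S1", "P1", "2018-01-01", "2018-01-05", [(1, "2018-01-01", ["J181"])])
        with pytest.raises(ValueError):
            classify_gold(s, mode="first_episode")


def _linked_frame(category_counts: dict[str, int], days: int = 3) -> pd.DataFrame:
    rows = []
    i = 0
    for category, count in category_counts.items():
        for _ in range(count):
            rows.append(
                {
                    "event_id": i,
                    "patient_id": f"P{i}",
                    "index_date": pd.Timestamp("2017-03-01"),
                    "spell_id": f"S{i}",
                    "admission_date": pd.Timestamp("2017-03-01") + pd.Timedelta(days=days),
                    "days_to_admission": days,
                    "primary_category": category,
                    "any_position_pneumonia": category == "pneumonia",
                }
            )
            i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "patient_id",
            "index_date",
            "spell_id",
            "admission_date",
            "days_to_admission",
            "primary_category",
            "any_position_pneumonia",
        ],
    )


class TestPPVArithmetic:
    def test_confirmed_over_linked(self):
        linked = _linked_frame({"pneumonia": 29, "copd": 11, "other": 10})
        events = simple_events([(i, f"P{i}", "2017-03-01") for i in range(60)])
        row = compute_ppv(events, linked, algorithm_by_id(1))
        assert (row.events, row.admitted, row.confirmed) == (60, 50, 29)
        assert row.estimate.percent == 58.0

    def test_zero_numerator(self):
        linked = _linked_frame({"copd": 5})
        events = simple_events([(i, f"P{i}", "2017-03-01") for i in range(5)])
        row = compute_ppv(events, linked, algorithm_by_id(1))
        assert row.estimate.percent == 0.0
        assert row.estimate.ci_low == 0.0

    def test_empty_denominator_renders_censored(self):
        events = simple_events([(0, "P0", "2017-03-01")])
        row = compute_ppv(events, _linked_frame({}), algorithm_by_id(1))
        assert row.estimate is None
        assert row.render_row()["ppv"] == "-"

    def test_same_day_restriction_subsets_denominator(self):
        linked = pd.concat(
            [_linked_frame({"pneumonia": 6}, days=0), _linked_frame({"copd": 4}, days=2)]
        )
        linked["event_id"] = range(10)
        linked["patient_id"] = [f"P{i}" for i in range(10)]
        events = simple_events([(i, f"P{i}", "2017-03-01") for i in range(10)])
        full = compute_ppv(events, linked, algorithm_by_id(1))
        same_day = compute_ppv(events, linked, algorithm_by_id(1), same_day_only=True)
        assert (full.admitted, same_day.admitted) == (10, 6)
        assert same_day.confirmed == 6

    def test_any_position_mode_never_lowers_ppv(self):
        linked = _linked_frame({"pneumonia": 10, "copd": 10})
        linked.loc[linked["primary_category"] == "copd", "any_position_pneumonia"] = [
            True, False, False, False, False, False, False, False, False, False,
        ]
        events = simple_events([(i, f"P{i}", "2017-03-01") for i in range(20)])
        primary = compute_ppv(events, linked, algorithm_by_id(1), gold_mode="primary_last_episode")
        any_pos = compute_ppv(events, linked, algorithm_by_id(1), gold_mode="any_position_last_episode")
        assert any_pos.confirmed == primary.confirmed + 1


class TestBreakdown:
    def test_reported_shares(self):
        linked = _linked_frame(
            {"pneumonia": 1208, "copd": 284, "other_respiratory": 114, "circulatory": 109, "other": 379}
        )
        shares = breakdown_nonpneumonia(linked)
        assert shares["copd"].k == 284
        # 284/886 = 32.054% -> 32.1 under half-up (printed tables truncate to 32.0)
        assert shares["copd"].percent == 32.1
        assert shares["other_respiratory"].percent == 12.9
        assert shares["circulatory"].percent == 12.3
        assert sum(e.k for e in shares.values()) == 886

    def test_empty_when_no_nonpneumonia(self):
        assert breakdown_nonpneumonia(_linked_frame({"pneumonia": 4})) == {}


class TestHospitalEvents:
    WINDOWS = make_windows([("P1", "2015-01-01", "2019-12-31")])

    def test_pneumonia_primary_inside_window_included(self):
        s = spell("S1", "P1", "2017-05-01", "2017-05-09", [(1, "2017-05-01", ["J159"])])
        out = find_hospital_pneumonia_events(build_gold_table([s]), self.WINDOWS)
        assert list(out["spell_id"]) == ["S1"]

    def test_admission_after_window_end_excluded(self):
        s = spell("S1", "P1", "2020-01-01", "2020-01-05", [(1, "2020-01-01", ["J181"])])
        out = find_hospital_pneumonia_events(build_gold_table([s]), self.WINDOWS)
        assert out.empty

    def test_window_end_boundary_included(self):
        s = spell("S1", "P1", "2019-12-31", "2020-01-04", [(1, "2019-12-31", ["J181"])])
        out = find_hospital_pneumonia_events(build_gold_table([s]), self.WINDOWS)
        assert len(out) == 1

    def test_copd_primary_excluded(self):
        s = spell("S1", "P1", "2017-05-01", "2017-05-09", [(1, "2017-05-01", ["J440"])])
        out = find_hospital_pneumonia_events(build_gold_table([s]), self.WINDOWS)
        assert out.empty


class TestRecording:
    def hospital_event(self):
        s = spell("S1", "P1", "2018-01-01", "2018-01-06", [(1, "2018-01-01", ["J181"])])
        return find_hospital_pneumonia_events(
            build_gold_table([s]), make_windows([("P1", "2015-01-01", "2019-12-31")])
        )

    def observations(self, rows):
        return make_dataset([patient_row("P1")], rows).observations

    def test_day_42_boundary_recorded(self, bundle):
        obs = self.observations([obs_row("P1", "PNEU001", "2018-02-12", "2018-02-20")])
        assert check_gp_recording(self.hospital_event(), obs, bundle).iloc[0]

    def test_day_43_not_recorded(self, bundle):
        obs = self.observations([obs_row("P1", "PNEU001", "2018-02-13")])
        assert not check_gp_recording(self.hospital_event(), obs, bundle).iloc[0]

    def test_code_before_admission_does_not_count(self, bundle):
        obs = self.observations([obs_row("P1", "PNEU001", "2017-12-31")])
        assert not check_gp_recording(self.hospital_event(), obs, bundle).iloc[0]

    def test_hosp_code_required_in_paired_mode(self, bundle):
        lone = self.observations([obs_row("P1", "PNEU001", "2018-01-11")])
        paired = self.observations(
            [obs_row("P1", "PNEU001", "2018-01-11"), obs_row("P1", "HOSP003", "2018-01-11")]
        )
        off_day = self.observations(
            [obs_row("P1", "PNEU001", "2018-01-11"), obs_row("P1", "HOSP003", "2018-01-12")]
        )
        ev = self.hospital_event()
        assert not check_gp_recording(ev, lone, bundle, mode="code_plus_hosp").iloc[0]
        assert check_gp_recording(ev, paired, bundle, mode="code_plus_hosp").iloc[0]
        assert not check_gp_recording(ev, off_day, bundle, mode="code_plus_hosp").iloc[0]

    def test_unknown_mode_rejected(self, bundle):
        with pytest.raises(ValueError):
            check_gp_recording(self.hospital_event(), self.observations([]), bundle, mode="x")


class TestSensitivityArithmetic:
    def test_counts_to_estimate(self):
        events = pd.DataFrame({"spell_id": [f"S{i}" for i in range(10)]})
        recorded = pd.Series([True] * 3 + [False] * 7)
        est = compute_sensitivity(events, recorded)
        assert (est.k, est.n, est.percent) == (3, 10, 30.0)

    def test_zero_denominator_undefined(self):
        assert compute_sensitivity(pd.DataFrame({"spell_id": []}), pd.Series(dtype=bool)) is None
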