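"""Survey cleaning, circular trait arithmetic, and 0-8 index scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepdex import sleep_index, times


def _minutes(hhmm: str) -> float:
    return times.parse_clock(hhmm)


class TestCleaning:
    def _survey(self, **overrides):
        base = {"participant_id": ["p1"],
                "weekday_bed": [_minutes("23:00")],
                "weekday_wake": [_minutes("07:00")],
                "weekend_bed": [_minutes("00:30")],
                "weekend_wake": [_minutes("08:00")]}
        base.update({k: [_minutes(v)] for k, v in overrides.items()})
        return pd.DataFrame(base)

    @pytest.mark.parametrize("field,value,removed", [
        ("weekday_bed", "09:00", True),    # morning bedtime: AM/PM misreport
        ("weekday_bed", "08:00", True),    # closed lower boundary
        ("weekday_bed", "14:00", True),    # closed upper boundary
        ("weekday_bed", "14:30", False),
        ("weekend_bed", "13:30", True),
        ("weekend_wake", "19:30", True),   # evening wake time
        ("weekday_wake", "18:00", True),
        ("weekday_wake", "00:00", False),  # midnight itself is retained
        ("weekday_wake", "17:30", False),
    ])
    def test_implausible_times_blanked(self, field, value, removed):
        cleaned = sleep_index.clean_survey(self._survey(**{field: value}))
        assert np.isnan(cleaned[field].iloc[0]) == removed

    def test_other_fields_untouched(self):
        survey = self._survey(weekday_bed="09:00")
        cleaned = sleep_index.clean_survey(survey)
        for col in ("weekday_wake", "weekend_bed", "weekend_wake"):
            assert cleaned[col].iloc[0] == survey[col].iloc[0]
        assert cleaned.attrs["cleaning_counts"]["weekday_bed"] == 1


class TestTimeInBed:
    @pytest.mark.parametrize("bed,wake,expected", [
        ("23:00", "07:00", 8.0),     # across midnight
        ("00:30", "08:00", 7.5),
        ("22:00", "20:00", np.nan),  # 22 h is implausible
        ("23:00", "01:00", np.nan),  # 2 h < 3 h floor
        ("21:00", "15:00", 18.0),    # closed upper bound kept
    ])
    def test_duration(self, bed, wake, expected):
        got = sleep_index.time_in_bed(_minutes(bed), _minutes(wake))
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_missing_propagates(self):
        assert np.isnan(sleep_index.time_in_bed(np.nan, _minutes("07:00")))

    @pytest.mark.parametrize("wd,we,expected", [
        (8.0, 9.0, 58 / 7), (8.0, 8.0, 8.0), (7.0, 10.5, 8.0)])
    def test_weekly_weighting(self, wd, we, expected):
        assert sleep_index.weighted_time_in_bed(wd, we) == pytest.approx(expected)


class TestMidpointAndJetlag:
    @pytest.mark.parametrize("bed,wake,expected", [
        ("23:00", "07:00", "03:00"),
        ("22:00", "04:00", "01:00"),  # midpoint crosses midnight
        ("01:00", "09:00", "05:00"),
    ])
    def test_midpoint(self, bed, wake, expected):
        got = sleep_index.sleep_midpoint(_minutes(bed), _minutes(wake))
        assert got == _minutes(expected)

    @pytest.mark.parametrize("a,b,expected", [
        ("03:00", "04:30", 1.5),
        ("23:00", "01:00", 2.0),   # circular, not 22 h
        ("03:00", "03:00", 0.0),
    ])
    def test_jetlag_is_circular(self, a, b, expected):
        assert sleep_index.social_jetlag(_minutes(a), _minutes(b)) == pytest.approx(expected)


GRID = st.integers(min_value=0, max_value=47).map(lambda k: k * 30.0)


class TestInvariants:
    @given(bed=GRID, wake=GRID, weekend_bed=GRID, weekend_wake=GRID,
           shift=st.integers(min_value=0, max_value=47))
    def test_clock_shift_invariance(self, bed, wake, weekend_bed, weekend_wake, shift):
        """Adding a constant to all clock inputs leaves durations unchanged."""
        dm = shift * 30.0

        def sh(t):
            return (t + dm) % 1440

        tib = sleep_index.time_in_bed(bed, wake)
        tib_s = sleep_index.time_in_bed(sh(bed), sh(wake))
        assert np.isnan(tib) == np.isnan(tib_s)
        if not np.isnan(tib):
            assert tib == pytest.approx(tib_s)
        m1 = times.midpoint_minutes(bed, wake)
        m2 = times.midpoint_minutes(weekend_bed, weekend_wake)
        sj = times.circular_distance_hours(m1, m2)
        sj_s = times.circular_distance_hours(
            times.midpoint_minutes(sh(bed), sh(wake)),
            times.midpoint_minutes(sh(weekend_bed), sh(weekend_wake)))
        assert sj == pytest.approx(sj_s)

    @given(st.lists(st.integers(min_value=0, max_value=1),
                    min_size=8, max_size=8),
           st.integers(min_value=0, max_value=7))
    def test_index_monotone_in_components(self, states, flip):
        """Turning any component favorable never decreases the index."""
        comp = pd.DataFrame([dict(zip(sleep_index.COMPONENTS, states))])
        comp.insert(0, "participant_id", ["p"])
        before = sleep_index.aggregate_index(comp)["index"].iloc[0]
        comp2 = comp.copy()
        comp2[sleep_index.COMPONENTS[flip]] = 1
        after = sleep_index.aggregate_index(comp2)["index"].iloc[0]
        assert after >= before


class TestScoring:
    def _traits(self, tw=8.0, irr=0.5, mid="03:00", sj=1.0):
        return pd.DataFrame({"participant_id": ["p"], "tib_weighted": [tw],
                             "tib_irregularity": [irr],
                             "midpoint_weekend": [_minutes(mid) if mid else np.nan],
                             "social_jetlag": [sj]})

    def _flags(self, insomnia="absent", breathing="absent", other="absent", med=False):
        return pd.DataFrame({"participant_id": ["p"],
                             "insomnia_disorder": [insomnia],
                             "breathing_disorder": [breathing],
                             "other_sleep_disorder": [other],
                             "sleep_medication": [med]})

    def test_boundary_conventions(self):
        """9.0 h is adequate (closed); 2.0 h jetlag is unfavorable (strict)."""
        comp = sleep_index.score_components(self._traits(tw=9.0, sj=2.0), self._flags())
        assert comp["adequate_tib"].iloc[0] == 1
        assert comp["low_social_jetlag"].iloc[0] == 0

    @pytest.mark.parametrize("mid,expected", [
        ("02:00", 1), ("04:00", 1), ("04:15", 0), ("01:45", 0)])
    def test_midpoint_window_closed(self, mid, expected):
        comp = sleep_index.score_components(self._traits(mid=mid), self._flags())
        assert comp["healthy_midpoint"].iloc[0] == expected

    def test_irregularity_strict_at_one_hour(self):
        comp = sleep_index.score_components(self._traits(irr=1.0), self._flags())
        assert comp["regular_tib"].iloc[0] == 0

    def test_single_code_flag_gives_missing_component_and_index(self):
        comp = sleep_index.score_components(
            self._traits(), self._flags(breathing="missing"))
        assert np.isnan(comp["no_breathing_disorder"].iloc[0])
        idx = sleep_index.aggregate_index(comp)
        assert np.isnan(idx["index"].iloc[0])

    @pytest.mark.parametrize("states,expected", [
        ([1] * 8, 8), ([0] * 8, 0), ([1, 0, 1, 0, 1, 0, 1, 0], 4)])
    def test_aggregate_counts_favorable(self, states, expected):
        comp = pd.DataFrame([dict(zip(sleep_index.COMPONENTS, states))])
        comp.insert(0, "participant_id", ["p"])
        assert sleep_index.aggregate_index(comp)["index"].iloc[0] == expected


def test_traits_pipeline_end_to_end():
    """A clean record flows through cleaning -> traits -> scoring unchanged."""
    survey = pd.DataFrame({
        "participant_id": ["p"],
        "weekday_bed": [_minutes("23:00")], "weekday_wake": [_minutes("07:00")],
        "weekend_bed": [_minutes("00:00")], "weekend_wake": [_minutes("08:30")],
    })
    flags = pd.DataFrame({"participant_id": ["p"], "insomnia_disorder": ["absent"],
                          "breathing_disorder": ["absent"],
                          "other_sleep_disorder": ["absent"],
                          "sleep_medication": [False]})
    traits, idx = sleep_index.build_sleep_index(survey, flags)
    assert traits["tib_weekday"].iloc[0] == pytest.approx(8.0)
    assert traits["tib_weekend"].iloc[0] == pytest.approx(8.5)
    assert traits["midpoint_weekend"].iloc[0] == _minutes("04:15")
    assert traits["social_jetlag"].iloc[0] == pytest.approx(1.25)
    # weighted tib 8.14 ok, irregularity 0.5 ok, midpoint 04:15 outside [2,4]
    assert idx["index"].iloc[0] == 7
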