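import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gendernet.cohort_data import (
    Cohort,
    InteractionRecord,
    Participant,
    ParseError,
    ReferentialIntegrityError,
    aggregate_weekly,
    filter_active,
    read_cohort,
    records_to_frame,
    weekly_average,
)
from gendernet.synthetic_cohort import GeneratorConfig, generate, write_fixture


class TestTypes:
    def test_gender_must_be_binary(self):
        with pytest.raises(ValueError):
            Participant("x", "other")

    def test_week_range_must_be_contiguous(self):
        with pytest.raises(ValueError):
            Cohort({"a": Participant("a", "F")}, week_range=[0, 2, 3])

    def test_active_weeks_must_lie_in_window(self):
        with pytest.raises(ValueError):
            Cohort({"a": Participant("a", "F", {9})}, week_range=[0, 1])

    def test_self_interactions_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord("call", 0, "a", "a", duration_s=10.0)

    def test_duration_present_iff_call(self):
        with pytest.raises(ValueError):
            InteractionRecord("text", 0, "a", "b", duration_s=10.0)
        with pytest.raises(ValueError):
            InteractionRecord("call", 0, "a", "b")


class TestAggregateWeekly:
    def test_reciprocal_records_sum_into_one_edge(self):
        recs = [
            InteractionRecord("proximity", 3, "u", "v", weight=1),
            InteractionRecord("proximity", 3, "v", "u", weight=2),
        ]
        series = aggregate_weekly(recs, "proximity")
        assert list(series.weekly_graphs) == [3]
        assert series.weekly_graphs[3]["u"]["v"]["weight"] == 3

    def test_separate_weeks_give_separate_graphs(self):
        recs = [
            InteractionRecord("text", 1, "u", "v", initiator_is_source=True),
            InteractionRecord("text", 2, "v", "w", initiator_is_source=False),
        ]
        series = aggregate_weekly(recs, "text")
        assert sorted(series.weekly_graphs) == [1, 2]
        assert all(g.number_of_edges() == 1 for g in series.weekly_graphs.values())
        # directed event list preserved with initiator resolution
        assert set(series.events["initiator"]) == {"u", "w"}

    def test_no_records_empty_series(self):
        series = aggregate_weekly([], "call")
        assert series.weekly_graphs == {}

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 3),  # week
                st.sampled_from(["a", "b", "c", "d"]),
                st.sampled_from(["a", "b", "c", "d"]),
                st.integers(1, 5),
            ).filter(lambda t: t[1] != t[2]),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_weight_conservation(self, raw):
        recs = [InteractionRecord("proximity", w, s, t, weight=k) for w, s, t, k in raw]
        series = aggregate_weekly(recs, "proximity")
        total = sum(
            d["weight"] for g in series.weekly_graphs.values() for _, _, d in g.edges(data=True)
        )
        assert total == sum(k for _, _, _, k in raw)


class TestFilterActive:
    def _cohort(self, weeks_per_id):
        return Cohort(
            {i: Participant(i, "M", set(w)) for i, w in weeks_per_id.items()},
            week_range=list(range(10)),
        )

    def test_three_active_weeks_excluded_four_retained(self):
        c = self._cohort({"x": [0, 1, 2], "y": [0, 1, 2, 3]})
        kept = filter_active(c, min_active_weeks=4)
        assert set(kept.participants) == {"y"}

    def test_all_inactive_gives_empty_cohort(self):
        kept = filter_active(self._cohort({"x": [], "y": []}))
        assert len(kept) == 0

    def test_idempotent(self):
        c = self._cohort({"x": [0, 1], "y": [0, 1, 2, 3, 4]})
        once = filter_active(c)
        twice = filter_active(once)
        assert set(once.participants) == set(twice.participants)


class TestWeeklyAverage:
    @pytest.mark.parametrize(
        "mapping,expected",
        [({1: 2.0, 2: 4.0}, 3.0), ({1: 5.0}, 5.0), ({1: 2.0, 2: float("nan")}, 2.0)],
    )
    def test_mean_over_defined_weeks(self, mapping, expected):
        assert weekly_average(mapping) == pytest.approx(expected)

    def test_empty_is_missing(self):
        assert math.isnan(weekly_average({}))


class TestReadCohort:
    def _write(self, tmp_path, participants, interactions, locations="", traits=""):
        files = {}
        files["participants"] = tmp_path / "participants.csv"
        files["participants"].write_text("id,gender\n" + participants)
        files["interactions"] = tmp_path / "interactions.csv"
        files["interactions"].write_text(
            "channel,week,source,target,weight,duration_s,initiator_is_source\n"
            + interactions
        )
        files["locations"] = tmp_path / "locations.csv"
        files["locations"].write_text("id,week,location_id,time_fraction\n" + locations)
        files["traits"] = tmp_path / "traits.csv"
        files["traits"].write_text("id,neuroticism\n" + traits)
        return files

    def test_two_participants_one_call(self, tmp_path):
        f = self._write(tmp_path, "a,F\nb,M\n", "call,0,a,b,1,42.0,1\n")
        data = read_cohort(*(f[k] for k in ("participants", "interactions", "locations", "traits")))
        assert len(data.cohort) == 2
        g = data.networks["call"].weekly_graphs[0]
        assert g.number_of_edges() == 1
        assert data.networks["call"].events["duration_s"].iloc[0] == 42.0

    def test_empty_interactions_valid(self, tmp_path):
        f = self._write(tmp_path, "a,F\nb,M\n", "")
        data = read_cohort(*(f[k] for k in ("participants", "interactions", "locations", "traits")))
        assert len(data.cohort) == 2
        assert all(s.weekly_graphs == {} for s in data.networks.values())

    def test_dangling_id_rejected(self, tmp_path):
        f = self._write(tmp_path, "a,F\nb,M\n", "call,0,a,zzz,1,10.0,1\n")
        with pytest.raises(ReferentialIntegrityError):
            read_cohort(*(f[k] for k in ("participants", "interactions", "locations", "traits")))

    def test_bad_gender_named_with_line(self, tmp_path):
        f = self._write(tmp_path, "a,F\nb,X\n", "")
        with pytest.raises(ParseError, match="gender"):
            read_cohort(*(f[k] for k in ("participants", "interactions", "locations", "traits")))

    def test_location_fractions_must_sum_to_one(self, tmp_path):
        f = self._write(tmp_path, "a,F\nb,M\n", "", locations="a,0,L1,0.4\na,0,L2,0.4\n")
        with pytest.raises(ParseError, match="sum"):
            read_cohort(*(f[k] for k in ("participants", "interactions", "locations", "traits")))


class TestRoundTrip:
    def test_write_read_write_is_byte_identical(self, tmp_path):
        data = generate(GeneratorConfig(n_female=8, n_male=20, n_weeks=3, seed=7))
        first = write_fixture(data, tmp_path / "one")
        loaded = read_cohort(
            first["participants"], first["interactions"], first["locations"], first["traits"]
        )
        # genders and structure survive
        assert loaded.cohort.genders() == data.cohort.genders()
        for ch, series in data.networks.items():
            for week, g in series.weekly_graphs.items():
                g2 = loaded.networks[ch].weekly_graphs[week]
                assert set(g.edges) == set(g2.edges)
        # re-serialize from the loaded model: identical bytes
        data2 = generate(GeneratorConfig(n_female=8, n_male=20, n_weeks=3, seed=7))
        data2.traits = loaded.traits
        data2.locations = loaded.locations
        data2.interactions = loaded.interactions
        second = write_fixture(data2, tmp_path / "two")
        for key in ("participants", "interactions", "locations", "traits"):
            assert first[key].read_bytes() == second[key].read_bytes()
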