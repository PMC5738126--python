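import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import labeled_graph
from oracles import brute_betweenness, brute_motifs

from gendernet.cohort_data import Cohort, InteractionRecord, Participant, aggregate_weekly
from gendernet.network_metrics import (
    active_dyad_fraction,
    betweenness,
    betweenness_all,
    call_duration_stats,
    count_motifs,
    degree,
    interaction_entropy,
    network_indicator_table,
    same_gender_fraction,
)
from gendernet.synthetic_cohort import (
    ChannelProfile,
    GeneratorConfig,
    LocationProfile,
    expected_same_gender_fraction,
    generate,
)


class TestDegreeAndSameGenderFraction:
    def test_mixed_neighborhood(self):
        g = labeled_graph(
            [("x", "a"), ("x", "b"), ("x", "c")],
            {"x": "F", "a": "F", "b": "F", "c": "M"},
        )
        assert degree(g, "x") == 3
        assert same_gender_fraction(g, "x") == pytest.approx(2 / 3)

    def test_isolate_fraction_missing_not_zero(self):
        g = labeled_graph([], {"x": "F"})
        assert degree(g, "x") == 0
        assert math.isnan(same_gender_fraction(g, "x"))

    def test_all_female_clique(self):
        nodes = {f"f{i}": "F" for i in range(4)}
        g = labeled_graph(
            [(a, b) for a in nodes for b in nodes if a < b], nodes
        )
        assert all(same_gender_fraction(g, n) == 1.0 for n in nodes)

    def test_unknown_gender_alters_excluded(self):
        g = labeled_graph([("x", "a"), ("x", "alter")], {"x": "F", "a": "F"})
        g.nodes["alter"]["gender"] = None
        assert degree(g, "x") == 2  # total degree counts the alter
        assert same_gender_fraction(g, "x") == 1.0  # homophily ignores it


class TestBetweenness:
    def test_path_middle_node(self):
        g = nx.path_graph(["a", "b", "c"])
        assert betweenness(g, "b") == pytest.approx(1.0)

    def test_star_center_counts_leaf_pairs(self):
        g = nx.star_graph(3)
        assert betweenness(g, 0) == pytest.approx(3.0)

    def test_four_cycle(self):
        g = nx.cycle_graph(4)
        for n in g:
            assert betweenness(g, n) == pytest.approx(0.5)

    def test_matches_bfs_brute_force_on_random_graphs(self):
        """Exact agreement with an all-pairs BFS path-counting oracle on 100
        random graphs of up to 25 nodes (including disconnected ones)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 26))
            p = float(rng.uniform(0.05, 0.6))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 31)))
            expected = brute_betweenness(list(g.nodes), list(g.edges))
            got = betweenness_all(g)
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-9)


class TestInteractionEntropy:
    def test_uniform_four_contacts_two_bits(self):
        assert interaction_entropy({i: 0.25 for i in range(4)}) == pytest.approx(2.0, abs=1e-9)

    def test_single_contact_zero(self):
        assert interaction_entropy({"v": 1.0}) == pytest.approx(0.0, abs=1e-12)

    def test_hand_summed_weights(self):
        assert interaction_entropy({"a": 2, "b": 1, "c": 1}) == pytest.approx(1.5, abs=1e-9)

    def test_empty_ego_network_missing(self):
        assert math.isnan(interaction_entropy({}))

    def test_bounded_by_log2_degree(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 9))
            w = {i: float(rng.uniform(0.1, 5)) for i in range(k)}
            assert interaction_entropy(w) <= math.log2(k) + 1e-9


class TestMotifs:
    def test_single_ff_edge(self):
        g = labeled_graph([("a", "b")], {"a": "F", "b": "F"})
        mc = count_motifs(g)
        assert mc.dyads == {"FF": 1, "MM": 0, "FM": 0}

    def test_all_female_triangle(self):
        g = labeled_graph([("a", "b"), ("b", "c"), ("a", "c")],
                          {"a": "F", "b": "F", "c": "F"})
        assert count_motifs(g).triads == {"FFF": 1, "MMM": 0, "mixed": 0}

    def test_k4_two_f_two_m_all_triangles_mixed(self):
        genders = {"a": "F", "b": "F", "c": "M", "d": "M"}
        g = labeled_graph(
            [(x, y) for x in genders for y in genders if x < y], genders
        )
        assert count_motifs(g).triads == {"FFF": 0, "MMM": 0, "mixed": 4}

    def test_unlabeled_node_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            count_motifs(g)

    def test_conservation_against_brute_force(self, rng):
        """Dyad counts sum to |E| and triad counts to the brute-force triangle
        total on random labeled graphs up to 30 nodes."""
        for _ in range(25):
            n = int(rng.integers(3, 31))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 31)))
            genders = {v: ("F" if rng.random() < 0.4 else "M") for v in g}
            nx.set_node_attributes(g, genders, "gender")
            mc = count_motifs(g)
            dyads, triads = brute_motifs(list(g.nodes), list(g.edges), genders)
            assert mc.dyads == dyads
            assert mc.triads == triads
            assert sum(mc.dyads.values()) == g.number_of_edges()


class TestActiveDyadFraction:
    @pytest.mark.parametrize(
        "graph,n,expected",
        [
            (nx.complete_graph(4), 4, 1.0),
            (nx.empty_graph(10), 10, 0.0),
            (nx.path_graph(4), 5, 0.3),  # 3 edges among 5 participants
        ],
    )
    def test_ratio(self, graph, n, expected):
        assert active_dyad_fraction(graph, n) == pytest.approx(expected)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            active_dyad_fraction(nx.Graph(), 1)


class TestCallDurations:
    genders = {"m1": "M", "m2": "M", "f1": "F", "f2": "F"}

    def _events(self, rows):
        return pd.DataFrame(rows, columns=["week", "initiator", "receiver", "weight", "duration_s"])

    def test_male_to_female_mean(self):
        ev = self._events([(0, "m1", "f1", 1, 100.0), (1, "m2", "f2", 1, 134.0)])
        stats = call_duration_stats(ev, self.genders)
        assert stats["MF"] == pytest.approx(117.0)

    def test_single_event_stratum(self):
        ev = self._events([(0, "f1", "f2", 1, 60.0)])
        stats = call_duration_stats(ev, self.genders)
        assert stats["FF"] == pytest.approx(60.0)
        assert math.isnan(stats["MM"])

    def test_empty_events(self):
        stats = call_duration_stats(self._events([]), self.genders)
        assert all(math.isnan(v) for v in stats.values())


class TestNetworkIndicatorTable:
    def _cohort(self):
        return Cohort(
            {i: Participant(i, g, {0, 1, 2, 3})
             for i, g in [("a", "F"), ("b", "M"), ("c", "M")]},
            week_range=list(range(4)),
        )

    def test_weekly_degree_average(self):
        cohort = self._cohort()
        recs = [
            InteractionRecord("call", 0, "a", "b", duration_s=5.0, initiator_is_source=True),
            InteractionRecord("call", 1, "a", "b", duration_s=5.0, initiator_is_source=True),
            InteractionRecord("call", 1, "a", "c", duration_s=5.0, initiator_is_source=True),
            InteractionRecord("call", 1, "b", "c", duration_s=5.0, initiator_is_source=True),
        ]
        networks = {"call": aggregate_weekly(recs, "call", cohort)}
        table = network_indicator_table(cohort, networks)
        assert table.loc["a", "call_degree"] == pytest.approx((1 + 2) / 2)

    def test_empty_channel_gives_missing_columns(self):
        cohort = self._cohort()
        networks = {"proximity": aggregate_weekly([], "proximity", cohort)}
        table = network_indicator_table(cohort, networks)
        assert table["proximity_degree"].isna().all()

    def test_planted_homophily_raises_same_gender_fraction(self):
        cfg = GeneratorConfig(
            n_female=30,
            n_male=70,
            n_weeks=2,
            channel_profiles={"proximity": ChannelProfile(0.15, 0.5)},
            location_profiles={"F": LocationProfile(2, 1.0), "M": LocationProfile(2, 1.0)},
            missing_rate=0.0,
            seed=11,
        )
        data = generate(cfg)
        table = network_indicator_table(data.cohort, data.networks)
        observed = table["proximity_same_gender_fraction"].mean()
        random_mixing = expected_same_gender_fraction(30, 70, 0.0)
        assert observed > random_mixing
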