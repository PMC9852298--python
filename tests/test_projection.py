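"""Signed projection, triad census, rolling windows and network comparison."""

import itertools

import pytest

import biproj as bp
from biproj.projection import SignedNetwork, ValidatedEdge
from oracles import signed_triangles

TYPES = bp.TABLE1_TYPES


def _random_typed_network(rng, n_agents=5, n_events=60, p_connect=0.6):
    events = [f"e{k}" for k in range(n_events)]
    records = []
    for a in range(n_agents):
        for e in events:
            if rng.random() < p_connect:
                records.append((f"agent{a}", e, TYPES.types[rng.integers(0, 3)]))
    return bp.load_incidence(records, TYPES, events=events)


class TestValidatePair:
    def test_worked_example_positive_and_negative(self, table1):
        p_pos, stats = bp.validate_pair(table1, "i", "j", "positive")
        assert p_pos == pytest.approx(0.9667, abs=1e-4)
        assert stats.same_type == 2
        p_neg, _ = bp.validate_pair(table1, "i", "j", "negative")
        assert p_neg == pytest.approx(1.70e-7, rel=5e-3)

    def test_zero_overlap_never_significant(self):
        records = [("a", "e1", "a1"), ("b", "e2", "a1")]
        net = bp.load_incidence(records, TYPES, events=[f"e{k}" for k in range(10)])
        p, stats = bp.validate_pair(net, "a", "b", "positive")
        assert p == 1.0 and stats.same_type == 0

    def test_symmetry_is_bit_for_bit(self, table1, rng):
        for mode in ("positive", "negative"):
            p_ij, _ = bp.validate_pair(table1, "i", "j", mode)
            p_ji, _ = bp.validate_pair(table1, "j", "i", mode)
            assert p_ij == p_ji
        net = _random_typed_network(rng)
        for a, b in itertools.combinations([f"agent{k}" for k in range(5)], 2):
            assert bp.validate_pair(net, a, b)[0] == bp.validate_pair(net, b, a)[0]

    def test_event_label_shuffle_leaves_pvalues_unchanged(self, rng):
        net = _random_typed_network(rng)
        perm = rng.permutation(net.n_events)
        relabel = {net.events[k]: net.events[perm[k]] for k in range(net.n_events)}
        shuffled = bp.load_incidence(
            [(a, relabel[e], t) for (a, e), t in net.incidence.items()],
            TYPES,
            events=net.events,
        )
        for a, b in [("agent0", "agent1"), ("agent2", "agent4")]:
            assert bp.validate_pair(net, a, b)[0] == pytest.approx(
                bp.validate_pair(shuffled, a, b)[0], rel=1e-12
            )

    def test_degree_zero_agent_is_an_error(self):
        net = bp.load_incidence([("a", "e1", "a1")], TYPES, agents=("a", "b"))
        with pytest.raises(ValueError, match="zero-degree"):
            bp.validate_pair(net, "a", "b")


class TestReferenceNull:
    def test_worked_example_per_type(self, table1):
        pvals = bp.validate_pair_reference(table1, "i", "j", aggregation="none")
        assert pvals[0] == pytest.approx(3.58e-3, rel=5e-3)
        assert pvals[1] == 1.0 and pvals[2] == 1.0

    def test_min_aggregation(self, table1):
        assert bp.validate_pair_reference(table1, "i", "j", "min") == pytest.approx(
            3.58e-3, rel=5e-3
        )

    def test_zero_overlap_every_type_gives_one(self):
        records = [("a", "e1", "a1"), ("b", "e2", "a2")]
        net = bp.load_incidence(records, TYPES, events=[f"e{k}" for k in range(5)])
        for agg in ("min", "mean", "max"):
            assert bp.validate_pair_reference(net, "a", "b", agg) == 1.0


class TestProject:
    def test_worked_example_yields_single_negative_edge(self, table1):
        snet = bp.project(table1, alpha=0.01, modes=("positive", "negative"))
        assert len(snet.edges) == 1
        (edge,) = snet.edges
        assert edge.sign == "negative"
        assert edge.p_value == pytest.approx(1.70e-7, rel=5e-3)
        assert snet.n_tests == {"positive": 1, "negative": 1}

    def test_vanishing_alpha_removes_all_edges(self, table1):
        snet = bp.project(table1, alpha=1e-300)
        assert snet.edges == ()

    def test_matches_pairwise_manual_thresholding(self, rng):
        net = _random_typed_network(rng, n_agents=4, n_events=40)
        agents = sorted(f"agent{k}" for k in range(4))
        alpha, m = 0.2, 6
        expected = set()
        for a, b in itertools.combinations(agents, 2):
            for mode in ("positive", "negative"):
                p, _ = bp.validate_pair(net, a, b, mode)
                if p <= alpha / m:
                    expected.add((a, b, mode))
        snet = bp.project(net, alpha=alpha, modes=("positive", "negative"))
        assert snet.edge_keys() == expected

    def test_edge_sets_nest_with_alpha(self, rng):
        net = _random_typed_network(rng, n_agents=6, n_events=50)
        keys = [
            bp.project(net, alpha=a, correction="bonferroni").edge_keys()
            for a in (1e-6, 1e-3, 1e-2, 0.5)
        ]
        for smaller, larger in zip(keys, keys[1:]):
            assert smaller <= larger

    def test_reference_model_only_positive_edges(self, table1):
        snet = bp.project(table1, alpha=0.05, model="reference-min")
        assert all(e.sign == "positive" for e in snet.edges)
        # the a1 overlap is significant under the per-type reference null
        assert len(snet.edges) == 1
        assert snet.edges[0].p_value == pytest.approx(3.58e-3, rel=5e-3)


def _signed_network_from(edges: dict[tuple[str, str], int], pvals=None) -> SignedNetwork:
    nodes = tuple(sorted({n for pair in edges for n in pair}))
    validated = tuple(
        ValidatedEdge(a, b, "positive" if s > 0 else "negative",
                      0.001 if pvals is None else pvals[(a, b)])
        for (a, b), s in sorted(edges.items())
    )
    return SignedNetwork(nodes=nodes, edges=validated, alpha=0.01, correction="none")


class TestTriadCensus:
    def test_all_positive_triangle_is_stable(self):
        census = bp.triad_census(
            _signed_network_from({("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1})
        )
        assert census.ppp == 1 and census.stable_total == 1 and census.unstable_total == 0

    def test_two_positive_one_negative_is_unstable(self):
        census = bp.triad_census(
            _signed_network_from({("a", "b"): 1, ("a", "c"): 1, ("b", "c"): -1})
        )
        assert census.ppm == 1 and census.unstable_total == 1

    def test_complete_four_node_graph_matches_enumeration(self):
        edges = {
            ("a", "b"): 1, ("a", "c"): -1, ("a", "d"): 1,
            ("b", "c"): -1, ("b", "d"): -1, ("c", "d"): 1,
        }
        census = bp.triad_census(_signed_network_from(edges))
        oracle = signed_triangles(edges)
        assert (census.mmm, census.pmm, census.ppm, census.ppp) == (
            oracle[0], oracle[1], oracle[2], oracle[3]
        )
        assert census.total == 4

    def test_random_graphs_match_sign_product_rule(self, rng):
        for _ in range(20):
            nodes = [f"n{k}" for k in range(7)]
            edges = {
                pair: int(rng.choice([-1, 1]))
                for pair in itertools.combinations(nodes, 2)
                if rng.random() < 0.6
            }
            if not edges:
                continue
            census = bp.triad_census(_signed_network_from(edges))
            oracle = signed_triangles(edges)
            assert census.stable_total == oracle[3] + oracle[1]
            assert census.unstable_total == oracle[2] + oracle[0]

    def test_double_signed_pair_resolved_by_smaller_p(self):
        nodes = ("a", "b", "c")
        edges = (
            ValidatedEdge("a", "b", "positive", 1e-8),
            ValidatedEdge("a", "b", "negative", 1e-3),
            ValidatedEdge("a", "c", "positive", 1e-4),
            ValidatedEdge("b", "c", "positive", 1e-4),
        )
        snet = SignedNetwork(nodes=nodes, edges=edges, alpha=0.01, correction="none")
        assert bp.triad_census(snet).ppp == 1
        assert bp.triad_census(snet, pair_resolution="negative").ppm == 1


class TestRollingWindow:
    def test_full_width_window_reproduces_static_projection(self, table1):
        df = bp.rolling_window_projection(table1, window_size=100, step=30)
        assert df["window"].nunique() == 1
        p_full, _ = bp.validate_pair(table1, "i", "j", "positive")
        assert df["p_value"].iloc[0] == pytest.approx(p_full, rel=1e-12)

    def test_window_arithmetic(self, rng):
        net = _random_typed_network(rng, n_agents=3, n_events=300)
        df = bp.rolling_window_projection(net, window_size=120, step=30)
        starts = sorted(df["start"].unique())
        assert starts == [0, 30, 60, 90, 120, 150, 180]

    def test_oversized_window_is_an_error(self, table1):
        with pytest.raises(ValueError, match="exceeds"):
            bp.rolling_window_projection(table1, window_size=101, step=10)

    def test_stationary_pair_has_flat_median_pvalue(self, rng):
        # fixed profiles: the median p-value should not drift across windows
        net = _random_typed_network(rng, n_agents=2, n_events=600, p_connect=0.7)
        df = bp.rolling_window_projection(net, window_size=200, step=100)
        medians = df.groupby("window")["p_value"].median()
        assert medians.max() - medians.min() < 0.9  # no systematic collapse


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = _signed_network_from({("a", "b"): 1, ("b", "c"): 1})
        b = _signed_network_from({("a", "b"): 1, ("b", "c"): 1})
        assert bp.jaccard_links(a, b).jaccard == 1.0
        c = _signed_network_from({("c", "d"): 1})
        assert bp.jaccard_links(a, c).jaccard == 0.0

    def test_partial_overlap(self):
        a = _signed_network_from({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1})
        b = _signed_network_from({("a", "b"): 1, ("c", "d"): 1, ("d", "e"): 1})
        result = bp.jaccard_links(a, b)
        assert result.jaccard == pytest.approx(0.5)
        assert result.n_only_a == 1 and result.n_only_b == 1 and result.n_common == 2

    def test_sign_matters_in_comparison(self):
        a = _signed_network_from({("a", "b"): 1})
        b = _signed_network_from({("a", "b"): -1})
        assert bp.jaccard_links(a, b).jaccard == 0.0

    def test_both_empty_defined_as_identical(self, caplog):
        empty = SignedNetwork(nodes=("a",), edges=(), alpha=0.01, correction="none")
        with caplog.at_level("WARNING", logger="biproj.projection"):
            assert bp.jaccard_links(empty, empty).jaccard == 1.0


class TestEdgeListIO:
    def test_round_trip(self, table1, tmp_path):
        snet = bp.project(table1, alpha=0.01)
        path = tmp_path / "edges.tsv"
        bp.write_edges_tsv(snet, path)
        restored = bp.read_edges_tsv(path)
        assert restored.edge_keys() == snet.edge_keys()
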