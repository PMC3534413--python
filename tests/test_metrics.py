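"""Centrality definitions, moment summaries, components, distances, rank tests."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from dtnet.graph import PiNetwork
from dtnet.metrics import (
    component_report,
    compute_metric,
    degree_change_report,
    metric_summary,
    nearest_label_distance,
    ranksum_compare,
)
from dtnet.records import LabelSet

from conftest import random_adjacency
from oracles import brute_betweenness, brute_closeness


def net_from_edges(edges, isolated=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(isolated)
    return PiNetwork(graph=g)


class TestCentrality:
    def test_path_graph_definitions(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        assert compute_metric(net, "degree").values == {"A": 1.0, "B": 2.0, "C": 1.0}
        assert compute_metric(net, "betweenness").values == {"A": 0.0, "B": 1.0, "C": 0.0}
        cc = compute_metric(net, "closeness")
        assert cc["B"] == pytest.approx(1 / 2)
        assert cc["A"] == pytest.approx(1 / 3)

    def test_star_center_betweenness_counts_leaf_pairs(self):
        net = net_from_edges([("H", "A"), ("H", "B"), ("H", "C")])
        assert compute_metric(net, "betweenness")["H"] == pytest.approx(3.0)  # C(3,2)

    def test_four_cycle_splits_credit_between_tied_paths(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        bc = compute_metric(net, "betweenness")
        assert all(v == pytest.approx(0.5) for v in bc.values.values())

    def test_isolated_node_gets_zero_closeness(self):
        net = net_from_edges([("A", "B")], isolated=["Z"])
        cc = compute_metric(net, "closeness")
        assert cc["Z"] == 0.0 and cc["A"] == 1.0

    def test_empty_network_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            compute_metric(PiNetwork(graph=nx.Graph()), "degree")

    def test_matches_brute_force_enumeration(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            adj = random_adjacency(rng, n=int(rng.integers(5, 16)), p=0.25)
            g = nx.Graph()
            g.add_nodes_from(adj)
            g.add_edges_from((u, v) for u in adj for v in adj[u] if u < v)
            net = PiNetwork(graph=g)
            bc = compute_metric(net, "betweenness")
            cc = compute_metric(net, "closeness")
            bc_oracle = brute_betweenness(adj)
            cc_oracle = brute_closeness(adj)
            for v in adj:
                assert bc[v] == pytest.approx(bc_oracle[v], abs=1e-9)
                assert cc[v] == pytest.approx(cc_oracle[v], abs=1e-9)

    def test_degree_sums_to_twice_edges(self, rng):
        adj = random_adjacency(rng, 20, 0.2)
        g = nx.Graph((u, v) for u in adj for v in adj[u] if u < v)
        g.add_nodes_from(adj)
        net = PiNetwork(graph=g)
        deg = compute_metric(net, "degree")
        assert sum(deg.values.values()) == 2 * net.n_edges


class TestSummary:
    def test_symmetric_values(self):
        s = metric_summary({"a": 1.0, "b": 2.0, "c": 3.0})
        assert s.mean == 2 and s.median == 2 and s.skewness == pytest.approx(0.0)
        assert s.kurtosis == pytest.approx(1.5)  # m4/m2^2 = (2/3)/(4/9)
        assert s.sd == pytest.approx(1.0)

    def test_zero_variance_moments_are_nan(self):
        s = metric_summary({"a": 5.0, "b": 5.0, "c": 5.0})
        assert s.sd == 0.0
        assert math.isnan(s.skewness) and math.isnan(s.kurtosis)

    def test_restriction_and_empty_restriction(self):
        values = {"a": 1.0, "b": 10.0}
        assert metric_summary(values, {"b"}).mean == 10.0
        with pytest.raises(ValueError):
            metric_summary(values, {"z"})


class TestComponents:
    def test_equal_size_components_order_by_smallest_node(self):
        net = net_from_edges(
            [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")]
        )
        rep = component_report(net, LabelSet({"drug_target": {"X"}}))
        assert rep.sizes == [3, 3]
        assert rep.components[0] == {"A", "B", "C"}  # tie broken by min node ID
        assert rep.disconnected == {"drug_target": 1}
        assert rep.label_counts[1]["drug_target"] == 1

    def test_connected_graph_has_no_disconnected_labels(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        rep = component_report(net, LabelSet({"drug_target": {"A", "C"}}))
        assert rep.disconnected == {"drug_target": 0}
        assert rep.n_disconnected_proteins == 0

    def test_label_absent_from_network_counts_zero(self):
        net = net_from_edges([("A", "B")])
        rep = component_report(net, LabelSet({"disease": {"Q"}}))
        assert rep.label_counts[0]["disease"] == 0
        assert rep.disconnected == {"disease": 0}


class TestDistances:
    def test_path_distance_and_membership_zero(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        prof = nearest_label_distance(net, {"A"}, {"C"})
        assert prof.distances == {"A": 2}
        prof = nearest_label_distance(net, {"A"}, {"A", "C"})
        assert prof.distances == {"A": 0}

    def test_unreachable_and_absent_buckets(self):
        net = net_from_edges([("A", "B"), ("X", "Y")])
        prof = nearest_label_distance(net, {"A", "Q"}, {"X"})
        assert prof.unreachable == {"A"}
        assert prof.absent == {"Q"}
        assert prof.histogram() == {}

    def test_distance_decreases_along_some_neighbor(self, rng):
        adj = random_adjacency(rng, 18, 0.15)
        g = nx.Graph()
        g.add_nodes_from(adj)
        g.add_edges_from((u, v) for u in adj for v in adj[u] if u < v)
        net = PiNetwork(graph=g)
        targets = {0, 1}
        prof = nearest_label_distance(net, set(adj), targets)
        for v, d in prof.distances.items():
            if d >= 1:
                assert any(prof.distances.get(u) == d - 1 for u in adj[v])


class TestRankSum:
    def test_exact_two_sided_p_for_separated_triples(self):
        res = ranksum_compare([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_identical_samples_give_p_one(self):
        assert ranksum_compare([1, 2], [1, 2]).p_value == 1.0
        assert ranksum_compare([0], [0]).p_value == 1.0

    def test_large_sample_uses_normal_approximation(self):
        a = list(range(40))
        b = list(range(5, 45))
        res = ranksum_compare(a, b)
        assert res.method == "normal"
        assert 0 < res.p_value < 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([], [1])


class TestDegreeChange:
    def test_mean_changes_per_group(self):
        rep = degree_change_report(
            {"a": 5.0, "b": 3.0}, {"a": 2.0, "b": 3.0}, {"a"}, {"b"}
        )
        assert rep.mean_change_a == -3.0 and rep.mean_change_b == 0.0

    def test_identical_maps_give_zero_change(self):
        full = {"a": 2.0, "b": 4.0}
        rep = degree_change_report(full, dict(full), {"a"}, {"b"})
        assert rep.mean_change_a == 0.0 and rep.mean_change_b == 0.0

    def test_exact_p_for_separated_changes(self):
        full = {c: 10.0 for c in "abcdef"}
        sub = {"a": 9.0, "b": 8.0, "c": 7.0, "d": 6.0, "e": 5.0, "f": 4.0}
        rep = degree_change_report(full, sub, {"a", "b", "c"}, {"d", "e", "f"})
        assert rep.p_value == pytest.approx(0.1)

    def test_missing_subset_nodes_count_as_zero_degree(self):
        rep = degree_change_report({"a": 5.0, "b": 1.0}, {"b": 1.0}, {"a"}, {"b"})
        assert rep.mean_change_a == -5.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            degree_change_report({"a": 1.0}, {"a": 1.0}, set(), {"a"})
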