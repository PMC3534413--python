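"""B/N/S classification, spoke/matrix expansion and network construction."""

from __future__ import annotations

import numpy as np
import pytest

from dtnet.graph import (
    SGroup,
    build_network,
    classify_records_bns,
    expand_record_edges,
    random_edge_subset,
    subnetwork_by_label,
)
from dtnet.records import Interactome

from conftest import mk_rec, random_interactome

NARY = {"m_nary"}


def shared_key(rid, pair, method="m_nary"):
    return mk_rec(rid, pair, source_db="db", pmid="p1", detection_method=method)


class TestClassification:
    def test_shared_hub_binaries_collapse_to_one_s_group(self):
        interactome = Interactome(
            [shared_key("r1", "AB"), shared_key("r2", "AC"), shared_key("r3", "AD")]
        )
        rc = classify_records_bns(interactome, NARY)
        assert rc.counts() == {"B": 0, "N": 0, "S": 3}
        (group,) = rc.s_groups
        assert group.members == {"A", "B", "C", "D"}
        assert group.hub == "A"
        assert group.record_ids == {"r1", "r2", "r3"}

    def test_non_nary_method_leaves_everything_binary(self):
        interactome = Interactome(
            [shared_key(r, p, "m_binary") for r, p in [("r1", "AB"), ("r2", "AC"), ("r3", "AD")]]
        )
        rc = classify_records_bns(interactome, NARY)
        assert rc.counts() == {"B": 3, "N": 0, "S": 0}
        assert rc.s_groups == []

    def test_lone_binary_under_nary_key_stays_b(self):
        # a lone binary record under an n-ary key has nothing to group with
        interactome = Interactome(
            [
                mk_rec("r1", "ABC", kind="complex", detection_method="m_nary"),
                shared_key("r2", "XY"),
            ]
        )
        rc = classify_records_bns(interactome, NARY)
        assert rc.assignment == {"r1": "N", "r2": "B"}
        assert rc.s_groups == []

    def test_protein_sharing_splits_groups_within_one_key(self):
        interactome = Interactome(
            [shared_key("r1", "AB"), shared_key("r2", "AC"),
             shared_key("r3", "XY"), shared_key("r4", "XZ")]
        )
        rc = classify_records_bns(interactome, NARY)
        assert len(rc.s_groups) == 2
        assert sorted(sorted(g.members) for g in rc.s_groups) == [
            ["A", "B", "C"], ["X", "Y", "Z"]
        ]

    def test_hub_falls_back_to_most_frequent_with_lexicographic_ties(self):
        # chain A-B, B-C, C-A: every protein appears twice, no common one
        interactome = Interactome(
            [shared_key("r1", "AB"), shared_key("r2", "BC"), shared_key("r3", "CA")]
        )
        rc = classify_records_bns(interactome, NARY)
        assert rc.s_groups[0].hub == "A"

    def test_empty_nary_set_forces_no_s_class(self, rng):
        interactome = random_interactome(rng)
        rc = classify_records_bns(interactome, set())
        assert rc.counts()["S"] == 0

    def test_assignment_is_a_partition(self, rng):
        for seed in range(10):
            interactome = random_interactome(np.random.default_rng(seed))
            rc = classify_records_bns(interactome, NARY)
            assert sum(rc.counts().values()) == len(interactome)
            s_assigned = rc.records_in_class("S")
            grouped = set().union(*(g.record_ids for g in rc.s_groups)) if rc.s_groups else set()
            assert s_assigned == grouped


class TestExpansion:
    def test_spoke_connects_hub_to_every_member(self):
        rec = mk_rec("r", "ABCD", kind="complex", hub_index=0)
        assert expand_record_edges(rec, "spoke") == {("A", "B"), ("A", "C"), ("A", "D")}

    def test_matrix_gives_all_pairs(self):
        rec = mk_rec("r", "ABCD", kind="complex")
        assert len(expand_record_edges(rec, "matrix")) == 6

    def test_binary_record_gives_its_single_pair_in_both_modes(self):
        rec = mk_rec("r", "AB")
        for mode in ("spoke", "matrix"):
            assert expand_record_edges(rec, mode) == {("A", "B")}

    @pytest.mark.parametrize("n", range(2, 21))
    def test_closed_forms_and_containment(self, n):
        members = [f"P{i:02d}" for i in range(n)]
        rec = mk_rec("r", members, kind="binary" if n == 2 else "complex", hub_index=0)
        spoke = expand_record_edges(rec, "spoke")
        matrix = expand_record_edges(rec, "matrix")
        assert len(spoke) == n - 1
        assert len(matrix) == n * (n - 1) // 2
        assert spoke <= matrix

    def test_self_pairs_are_dropped(self):
        group = SGroup(frozenset({"r"}), frozenset({"A", "B"}), "A", ("d", "p", "m"))
        assert expand_record_edges(group, "spoke") == {("A", "B")}

    def test_single_member_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            expand_record_edges(mk_rec("r", "A"), "spoke")


class TestBuildNetwork:
    def setup_method(self):
        self.interactome = Interactome(
            [mk_rec("r1", "AB"), mk_rec("r2", "ABC", kind="complex", hub_index=0)]
        )
        self.rc = classify_records_bns(self.interactome, NARY)

    def test_spoke_union_merges_duplicate_pairs_with_provenance(self):
        net = build_network(self.interactome, self.rc, "spoke", {"B", "N"})
        assert net.nodes == {"A", "B", "C"}
        assert set(net.edges()) == {("A", "B"), ("A", "C")} or set(
            tuple(sorted(e)) for e in net.edges()
        ) == {("A", "B"), ("A", "C")}
        assert net.edge_records("A", "B") == {"r1", "r2"}
        assert net.edge_records("A", "C") == {"r2"}

    def test_matrix_union(self):
        net = build_network(self.interactome, self.rc, "matrix", {"B", "N"})
        assert net.n_edges == 3

    def test_unselected_classes_give_empty_network(self):
        interactome = Interactome([mk_rec("r1", "AB")])
        rc = classify_records_bns(interactome, NARY)
        net = build_network(interactome, rc, "spoke", {"N"})
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_empty_class_selection_is_rejected(self):
        with pytest.raises(ValueError):
            build_network(self.interactome, self.rc, "spoke", set())

    def test_s_groups_expand_as_one_unit(self):
        interactome = Interactome(
            [shared_key("r1", "AB"), shared_key("r2", "AC"), shared_key("r3", "AD")]
        )
        rc = classify_records_bns(interactome, NARY)
        spoke = build_network(interactome, rc, "spoke", {"S"})
        assert set(map(tuple, map(sorted, spoke.edges()))) == {
            ("A", "B"), ("A", "C"), ("A", "D")
        }
        matrix = build_network(interactome, rc, "matrix", {"S"})
        assert matrix.n_edges == 6  # C(4,2): the unit is the derived member set

    def test_output_is_simple_and_matrix_contains_spoke(self):
        for seed in range(15):
            interactome = random_interactome(np.random.default_rng(seed), n_records=20)
            rc = classify_records_bns(interactome, NARY)
            spoke = build_network(interactome, rc, "spoke")
            matrix = build_network(interactome, rc, "matrix")
            for net in (spoke, matrix):
                assert all(u != v for u, v in net.edges())
            spoke_edges = {tuple(sorted(e)) for e in spoke.edges()}
            matrix_edges = {tuple(sorted(e)) for e in matrix.edges()}
            assert spoke_edges <= matrix_edges


class TestSubnetworks:
    def triangle(self):
        interactome = Interactome(
            [mk_rec("r1", "AB"), mk_rec("r2", "BC"), mk_rec("r3", "CA")]
        )
        rc = classify_records_bns(interactome, set())
        return build_network(interactome, rc, "spoke")

    def test_only_mode_induces_on_members(self):
        sub = subnetwork_by_label(self.triangle(), {"A", "B"}, "only")
        assert sub.nodes == {"A", "B"} and sub.n_edges == 1

    def test_isolated_labelled_nodes_are_kept(self):
        sub = subnetwork_by_label(self.triangle(), {"A"}, "only")
        assert sub.nodes == {"A"} and sub.n_edges == 0

    def test_exclude_mode(self):
        sub = subnetwork_by_label(self.triangle(), {"A"}, "exclude")
        assert sub.nodes == {"B", "C"} and sub.n_edges == 1

    def test_random_edge_subset_keeps_requested_fraction(self):
        net = self.triangle()
        sub = random_edge_subset(net, 2 / 3, seed=0)
        assert sub.n_edges == 2
        assert {tuple(sorted(e)) for e in sub.edges()} <= {
            tuple(sorted(e)) for e in net.edges()
        }
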