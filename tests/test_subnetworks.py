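"""Uniform/perturbed sub-network extraction, validated against brute force."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from helpers_bruteforce import oracle_attached_targets

from conftest import make_annotation_map, make_count_profile, random_problem
from netperturb.interactome import Interactome
from netperturb.subnetworks import (
    build_perturbed_networks,
    reachable_targets,
    uniform_subnetworks,
)


def net_from_edges(*edges: tuple[str, str]) -> Interactome:
    return Interactome(nx.Graph(list(edges)))


class TestUniformSubnetworks:
    def test_connected_annotated_path_is_one_component(self):
        net = net_from_edges(("A", "B"), ("B", "C"))
        am = make_annotation_map({"t": {"A", "B", "C"}})
        subs = uniform_subnetworks(net, am, "t")
        assert len(subs) == 1 and subs[0].members == {"A", "B", "C"}

    def test_same_term_can_have_disjoint_components(self):
        net = net_from_edges(("A", "B"), ("C", "D"), ("B", "X"), ("X", "C"))
        am = make_annotation_map({"t": {"A", "B", "C", "D"}})
        subs = uniform_subnetworks(net, am, "t")
        assert [s.members for s in subs] == [{"A", "B"}, {"C", "D"}]
        assert [s.component_index for s in subs] == [0, 1]

    def test_singleton_component_allowed(self):
        net = net_from_edges(("A", "X"), ("X", "B"))
        am = make_annotation_map({"t": {"A", "B"}})
        subs = uniform_subnetworks(net, am, "t")
        assert [s.members for s in subs] == [{"A"}, {"B"}]

    def test_min_size_floor(self):
        net = net_from_edges(("A", "B"), ("C", "X"))
        am = make_annotation_map({"t": {"A", "B", "C"}})
        subs = uniform_subnetworks(net, am, "t", min_size=2)
        assert [s.members for s in subs] == [{"A", "B"}]

    def test_unknown_term_is_an_error(self):
        net = net_from_edges(("A", "B"))
        with pytest.raises(KeyError):
            uniform_subnetworks(net, make_annotation_map({}), "t")


class TestReachableTargets:
    def test_chain_included_isolated_excluded(self):
        net = net_from_edges(("M", "T1"), ("T1", "T2"), ("T3", "X"))
        got = reachable_targets(net, {"M"}, {"T1", "T2", "T3"})
        assert got == {"T1", "T2"}

    def test_no_adjacent_targets(self):
        net = net_from_edges(("M", "X"), ("X", "T1"))
        assert reachable_targets(net, {"M"}, {"T1"}) == set()

    def test_three_link_chain_fully_included(self):
        net = net_from_edges(("M", "T1"), ("T1", "T2"), ("T2", "T3"))
        assert reachable_targets(net, {"M"}, {"T1", "T2", "T3"}) == {"T1", "T2", "T3"}

    def test_member_targets_included(self):
        net = net_from_edges(("M", "X"))
        assert reachable_targets(net, {"M"}, {"M"}) == {"M"}

    def test_targets_absent_from_net_ignored(self):
        net = net_from_edges(("M", "T1"))
        assert reachable_targets(net, {"M"}, {"T1", "GHOST"}) == {"T1"}

    def test_matches_path_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net, annotations, profile = random_problem(rng)
            members = next(iter(annotations.values())) & net.nodes
            targets = profile.target_ids
            got = reachable_targets(net, members, targets)
            want = oracle_attached_targets(net.graph, members, targets & net.nodes)
            assert got == want


class TestPerturbedNetworks:
    def test_shared_target_merges_disjoint_components(self):
        # two disjoint uniform components, one adjacent target linking them
        net = net_from_edges(("A", "B"), ("C", "D"), ("B", "T"), ("T", "C"))
        am = make_annotation_map({"t": {"A", "B", "C", "D"}})
        profile = make_count_profile([("T", 10, 0)])
        pnets = build_perturbed_networks(net, am, "t", profile)
        assert len(pnets) == 1
        assert pnets[0].nodes == {"A", "B", "C", "D", "T"}
        assert pnets[0].n_annot_net == 4 and pnets[0].n_drug_net == 1

    def test_component_without_targets_kept_with_zero_drug_count(self):
        net = net_from_edges(("A", "B"), ("X", "Y"))
        am = make_annotation_map({"t": {"A", "B"}})
        profile = make_count_profile([("X", 10, 0)])  # not adjacent to {A,B}
        pnets = build_perturbed_networks(net, am, "t", profile)
        assert len(pnets) == 1
        assert pnets[0].n_drug_net == 0
        assert pnets[0].nodes == {"A", "B"}

    def test_direct_target_counts_as_member_and_target(self):
        # uniform {A,B}; T peripheral on A; D a direct (annotated) target
        net = net_from_edges(("A", "D"), ("A", "T"))
        am = make_annotation_map({"t": {"A", "D"}})
        profile = make_count_profile([("T", 10, 0), ("D", 10, 0)])
        (pnet,) = build_perturbed_networks(net, am, "t", profile)
        assert pnet.n_net == 3
        assert pnet.n_annot_net == 2
        assert pnet.n_drug_net == 2
        assert "D" in pnet.annotated_members and "D" in pnet.target_members

    def test_union_of_annotated_members_covers_the_term(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net, annotations, profile = random_problem(rng)
            for term, members in annotations.items():
                am = make_annotation_map(annotations)
                pnets = build_perturbed_networks(net, am, term, profile)
                union = set().union(*(p.annotated_members for p in pnets)) if pnets else set()
                assert union == members & net.nodes

    def test_isolated_target_changes_nothing(self):
        net = net_from_edges(("A", "B"), ("B", "T"), ("Z", "Q"))
        am = make_annotation_map({"t": {"A", "B"}})
        with_iso = make_count_profile([("T", 10, 0), ("Z", 10, 0), ("LONE", 10, 0)])
        without = make_count_profile([("T", 10, 0), ("Z", 10, 0)])
        a = build_perturbed_networks(net, am, "t", with_iso)
        b = build_perturbed_networks(net, am, "t", without)
        assert [(p.nodes, p.edges) for p in a] == [(p.nodes, p.edges) for p in b]

    def test_induced_edges_are_exactly_the_internal_ones(self):
        net = net_from_edges(("A", "B"), ("B", "T"), ("T", "X"))
        am = make_annotation_map({"t": {"A", "B"}})
        profile = make_count_profile([("T", 10, 0)])
        (pnet,) = build_perturbed_networks(net, am, "t", profile)
        assert pnet.edges == {("A", "B"), ("B", "T")}
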