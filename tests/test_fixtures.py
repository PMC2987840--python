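"""Synthetic benchmark generator: determinism, planted truth, round trips."""

from __future__ import annotations

import math

import networkx as nx
import pytest

from netperturb.affinity import affinity_score, build_profile
from netperturb.annotation import propagate_ancestors
from netperturb.fixtures import (
    FixtureSpec,
    ModuleSpec,
    counts_from_affinity,
    generate_fixture,
    write_fixture_files,
)
from netperturb.interactome import build_interactome
from netperturb.io_formats import (
    read_annotations,
    read_edge_list,
    read_obo,
    read_target_profile,
)
from netperturb.scoring import score_all


class TestCountsFromAffinity:
    @pytest.mark.parametrize("a,p_t,expected_p_comp", [
        (0.0, 10, 10),
        (1.0, 10, 0),
        (0.5, 100, 75),
    ])
    def test_examples(self, a, p_t, expected_p_comp):
        got_p_t, got_p_comp = counts_from_affinity(a, p_t)
        assert (got_p_t, got_p_comp) == (p_t, expected_p_comp)

    def test_unreachable_affinity_is_an_error(self):
        with pytest.raises(ValueError):
            counts_from_affinity(1.5, 10)  # log10(10) = 1 < 1.5

    def test_round_trip_within_rounding_bound(self):
        for p_t in (2, 5, 10, 50, 100, 500):
            cap = math.log10(p_t)
            for frac in (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0):
                a = frac * cap
                recovered = affinity_score(*counts_from_affinity(a, p_t))
                assert abs(recovered - a) <= cap / p_t

    def test_single_peptide_only_represents_zero(self):
        assert counts_from_affinity(0.0, 1) == (1, 1)


class TestGenerator:
    def test_same_seed_reproduces_everything(self):
        a = generate_fixture(FixtureSpec(seed=5))
        b = generate_fixture(FixtureSpec(seed=5))
        assert a.net.edges == b.net.edges
        assert a.annotations.by_term == b.annotations.by_term
        assert [(t.protein_id, t.a_t) for t in a.profile.targets] == \
               [(t.protein_id, t.a_t) for t in b.profile.targets]
        assert a.truth.target_roles == b.truth.target_roles

    def test_different_seeds_differ(self):
        a = generate_fixture(FixtureSpec(seed=5))
        b = generate_fixture(FixtureSpec(seed=6))
        assert a.net.edges != b.net.edges

    @pytest.mark.parametrize("bad", [
        FixtureSpec(n_nodes=30, modules=(ModuleSpec(size=40),)),
        FixtureSpec(modules=(ModuleSpec(size=40, density=1.5),)),
        FixtureSpec(n_peripheral=-1),
        FixtureSpec(n_direct=50),
    ])
    def test_infeasible_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_fixture(bad)

    def test_planted_module_is_connected_and_annotated(self, standard_bundle):
        b = standard_bundle
        term = b.truth.planted_terms[0]
        members = set(b.truth.module_nodes[term])
        assert members == b.annotations.by_term[term]
        assert nx.is_connected(b.net.graph.subgraph(members))

    def test_ancestor_closure_in_generated_map(self, standard_bundle):
        b = standard_bundle
        term = b.truth.planted_terms[0]
        for parent in b.ontology.ancestors(term):
            assert b.annotations.by_term[term] <= b.annotations.by_term[parent]

    def test_ontology_depth_at_least_three(self, standard_bundle):
        term = standard_bundle.truth.planted_terms[0]
        assert len(standard_bundle.ontology.ancestors(term)) >= 2

    def test_decoy_terms_are_count_matched(self, standard_bundle):
        b = standard_bundle
        planted = b.truth.planted_terms[0]
        k = len(b.annotations.by_term[planted])
        decoys = [t for t in b.annotations.by_term
                  if b.annotations.term_names[t].startswith("decoy process")]
        assert len(decoys) == 10
        assert all(len(b.annotations.by_term[t]) == k for t in decoys)

    def test_target_roles_are_exact(self, standard_bundle):
        b = standard_bundle
        module = set(b.truth.module_nodes[b.truth.planted_terms[0]])
        roles = b.truth.target_roles
        for node, role in roles.items():
            neighbors = set(b.net.graph.neighbors(node))
            if role == "peripheral":
                assert neighbors <= module and len(neighbors) == 1
            elif role == "chained":
                # reaches the module directly or through the other chain link
                assert neighbors <= module | {n for n, r in roles.items()
                                              if r == "chained"}
        chain = [n for n, r in roles.items() if r == "chained"]
        attached = sum(1 for n, r in roles.items() if r in ("peripheral", "chained"))
        assert len(chain) == 2 and attached == 5

    def test_decoy_targets_carry_zero_affinity(self, standard_bundle):
        b = standard_bundle
        for node, role in b.truth.target_roles.items():
            a = b.profile.affinities[node]
            assert (a == 0.0) == (role == "decoy")

    def test_zero_target_spec_scores_nothing(self):
        spec = FixtureSpec(seed=2, n_peripheral=0, chain_length=0,
                           n_direct=0, n_decoy_targets=0)
        bundle = generate_fixture(spec)
        assert bundle.profile is None

    def test_zero_affinity_targets_only_score_zero(self):
        spec = FixtureSpec(seed=2, n_peripheral=0, chain_length=0, n_direct=0)
        b = generate_fixture(spec)  # only decoy targets remain
        results = score_all(b.net, b.annotations, b.profile, include_zero=True)
        assert all(r.s_net == 0.0 for r in results)


class TestOnDiskRoundTrip:
    def test_written_files_reproduce_the_bundle(self, standard_bundle, tmp_path):
        b = standard_bundle
        paths = write_fixture_files(b, tmp_path)
        assert sorted(p.name for p in paths.values()) == [
            "annotations.tsv", "edges.tsv", "ontology.obo", "profile.tsv",
            "truth.json"]
        net = build_interactome([read_edge_list(paths["edges"])])
        assert net.edges == b.net.edges
        ont = read_obo(paths["obo"])
        assert ont.terms == b.ontology.terms
        assert ont.parents == b.ontology.parents
        raw = read_annotations(paths["annotations"])
        am = propagate_ancestors(raw, ont, net)
        assert am.by_term == b.annotations.by_term
        rows = read_target_profile(paths["profile"])
        profile = build_profile(rows)
        assert profile.affinities == b.profile.affinities
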