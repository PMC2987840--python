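"""Shared fixtures: tiny hand-built inputs and one standard synthetic bundle."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netperturb.affinity import build_profile
from netperturb.annotation import AnnotationMap, Ontology
from netperturb.fixtures import FixtureSpec, generate_fixture
from netperturb.interactome import Interactome
from netperturb.io_formats import ProfileRow


@pytest.fixture(scope="session")
def standard_bundle():
    """The default synthetic benchmark (500 nodes, one planted module)."""
    return generate_fixture(FixtureSpec(seed=0))


@pytest.fixture
def toy_net() -> Interactome:
    """Path A-B-C-D plus a triangle E-F-G attached to D via E."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                      ("E", "F"), ("F", "G"), ("E", "G")])
    return Interactome(g)


@pytest.fixture
def chain_ontology() -> Ontology:
    """leaf is_a mid is_a root."""
    ont = Ontology()
    for term, name, parents in [
        ("GO:0000003", "leaf", {"GO:0000002"}),
        ("GO:0000002", "mid", {"GO:0000001"}),
        ("GO:0000001", "root", set()),
    ]:
        ont.names[term] = name
        ont.parents[term] = parents
        ont.part_of_parents[term] = set()
    return ont


def make_annotation_map(by_term: dict[str, set[str]]) -> AnnotationMap:
    by_node: dict[str, set[str]] = {}
    for term, nodes in by_term.items():
        for n in nodes:
            by_node.setdefault(n, set()).add(term)
    return AnnotationMap(by_term={t: set(ns) for t, ns in by_term.items()},
                         by_node=by_node)


def make_count_profile(rows: list[tuple[str, int, int]]):
    return build_profile([ProfileRow(pid, p_t=p, p_comp=c) for pid, p, c in rows])


def random_problem(rng: np.random.Generator):
    """One random tiny scoring problem: graph + annotations + profile.

    Graphs have at most 8 nodes; one profiled target may sit outside the
    graph so the affinity denominator covers unreachable targets too.
    """
    n = int(rng.integers(2, 9))
    p = float(rng.choice([0.2, 0.4, 0.6, 0.8]))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        g.add_edge("N0", "N1")
    nodes = sorted(g.nodes)
    annotations = {}
    for t in range(int(rng.integers(1, 4))):
        k = int(rng.integers(1, len(nodes) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        annotations[f"GO:{t:07d}"] = {nodes[i] for i in sorted(idx)}
    n_targets = int(rng.integers(0, 4))
    idx = rng.choice(len(nodes), size=min(n_targets, len(nodes)), replace=False)
    target_ids = [nodes[i] for i in sorted(idx)]
    if rng.random() < 0.3:
        target_ids.append("OFFGRAPH")  # in the profile, absent from the net
    rows = []
    for tid in target_ids:
        p_t = int(rng.integers(1, 50))
        p_comp = int(rng.integers(0, p_t + 3))
        rows.append((tid, p_t, p_comp))
    if not rows:
        rows = [("N0", 10, 0)]
    return Interactome(g), annotations, make_count_profile(rows)
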