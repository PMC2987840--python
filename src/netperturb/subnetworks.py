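"""Uniform and perturbed functional sub-networks.

A *uniform functional sub-network* is a connected fraction of the
interactome in which every protein shares one GO biological-process term.
A term can have several disjoint uniform sub-networks (the annotated nodes
need not be mutually connected). Singletons count: one annotated protein
plus its attached drug targets is a meaningful perturbed unit, though a
minimum-size floor can be imposed.

A drug perturbs a uniform sub-network in two ways, treated equally: by
directly inhibiting a member (direct targets are themselves annotated
members), or by acting at the periphery through a target interacting with a
member. To cover complexes and signaling cascades, targets connected to the
sub-network only through chains of other drug targets are included too.

The *perturbed functional sub-network* combines a term's annotated nodes
with every target attached this way, taking connected components of the
union. Attaching a shared target can fuse otherwise disjoint uniform
sub-networks of the same term into a single perturbed network — the target
acts as a linker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .affinity import TargetProfile
from .annotation import AnnotationMap
from .interactome import Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "UniformSubnetwork",
    "PerturbedNetwork",
    "uniform_subnetworks",
    "reachable_targets",
    "build_perturbed_networks",
]


@dataclass(frozen=True)
class UniformSubnetwork:
    """One connected component of a term's annotated nodes."""

    term: str
    members: frozenset[str]
    component_index: int


@dataclass(frozen=True)
class PerturbedNetwork:
    """One scored unit: annotated members plus attached drug targets.

    Direct targets (annotated members that are profiled targets) appear in
    both ``annotated_members`` and ``target_members``. ``edges`` is the full
    induced edge set, canonically ordered pairs.
    """

    term: str
    component_index: int
    annotated_members: frozenset[str]
    target_members: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return self.annotated_members | self.target_members

    @property
    def n_net(self) -> int:
        return len(self.nodes)

    @property
    def n_annot_net(self) -> int:
        return len(self.annotated_members)

    @property
    def n_drug_net(self) -> int:
        return len(self.target_members)


def _ordered_components(graph: nx.Graph) -> list[set[str]]:
    """Connected components ordered by lexicographically smallest member."""
    return sorted(nx.connected_components(graph), key=min)


def uniform_subnetworks(
    net: Interactome, am: AnnotationMap, term: str, min_size: int = 1
) -> list[UniformSubnetwork]:
    """Connected components of the subgraph induced on a term's nodes.

    Components smaller than ``min_size`` are discarded; component indices
    are assigned in order of lexicographically smallest member.
    """
    members = am.nodes_for(term)  # raises KeyError for unknown terms
    sub = net.graph.subgraph(members & net.nodes)
    return [
        UniformSubnetwork(term, frozenset(comp), idx)
        for idx, comp in enumerate(_ordered_components(sub))
        if len(comp) >= min_size
    ]


def reachable_targets(
    net: Interactome, members: Iterable[str], targets: Iterable[str]
) -> set[str]:
    """Targets attached to ``members`` directly or via target-only chains.

    A target belongs to the result iff some path connects it to a member
    with every interior node itself a target; equivalently, iff it is
    reachable from the member set within the subgraph induced on
    members ∪ targets. Members that are themselves targets are included.
    Targets absent from the interactome are ignored with a warning.
    """
    members = set(members)
    targets = set(targets)
    absent = targets - net.nodes
    if absent:
        logger.warning(
            "[subnetworks] %d profile target(s) absent from the interactome", len(absent)
        )
        targets = targets - absent
    sub = net.graph.subgraph(members | targets)
    seeds = members & set(sub.nodes)
    reached: set[str] = set()
    for comp in nx.connected_components(sub):
        if comp & seeds:
            reached |= comp & targets
    return reached


def build_perturbed_networks(
    net: Interactome,
    am: AnnotationMap,
    term: str,
    profile: TargetProfile,
    min_size: int = 1,
) -> list[PerturbedNetwork]:
    """Perturbed functional sub-networks of one term.

    Takes the union of the term's annotated nodes (uniform components of at
    least ``min_size`` members) with all reachable targets, and returns the
    connected components of the induced subgraph. Uniform components that
    share an attached target merge into one perturbed network (the linker
    effect). Components with no profiled target are still returned — they
    score 0 downstream.
    """
    uniform = uniform_subnetworks(net, am, term, min_size=min_size)
    members: set[str] = set().union(*(u.members for u in uniform)) if uniform else set()
    if not members:
        return []
    attached = reachable_targets(net, members, profile.target_ids)
    sub = net.graph.subgraph(members | attached)
    nets: list[PerturbedNetwork] = []
    for idx, comp in enumerate(_ordered_components(sub)):
        edges = frozenset(
            (a, b) if a <= b else (b, a) for a, b in sub.subgraph(comp).edges
        )
        nets.append(
            PerturbedNetwork(
                term=term,
                component_index=idx,
                annotated_members=frozenset(comp & members),
                target_members=frozenset(comp & attached),
                edges=edges,
            )
        )
    return nets
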