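"""The merged undirected protein interaction network.

The interactome is the substrate for every downstream step: functional
sub-networks are connected fractions of it, drug targets attach to it, and
the randomization null rewires it. It is a simple undirected graph over
protein identifiers — no self-loops, no parallel edges, no weights.

Identifier handling is deliberately strict: node identity is case-sensitive
exact string match, and no mapping between identifier namespaces (UniProt,
Entrez, gene symbols) is attempted. All input files must share a single
namespace. Proteins appearing only in annotation or profile files, but in no
interaction, are not interactome members — they can never join a connected
sub-network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import EdgeRecord

logger = logging.getLogger(__name__)

__all__ = ["Interactome", "build_interactome", "degree", "induced_subgraph"]


@dataclass
class Interactome:
    """A simple undirected graph over protein identifiers.

    Wraps a :class:`networkx.Graph`; the wrapper guarantees the domain
    invariants (no self-loops, unordered-deduplicated edges) at construction
    time so downstream code never needs to re-check them.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"interactome must not contain self-loops: {loops[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set as canonically ordered (min, max) tuples."""
        return {(a, b) if a <= b else (b, a) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def degree(self, node: str) -> int:
        return degree(self, node)

    def induced_subgraph(self, nodes: Iterable[str]) -> "Interactome":
        return induced_subgraph(self, nodes)


def build_interactome(edge_sets: Iterable[Iterable["EdgeRecord"]]) -> Interactome:
    """Merge one or more edge-record collections into a single network.

    Edges are deduplicated as unordered pairs across all sources; the node
    set is the union of all edge endpoints. Raises ``ValueError`` when the
    merged result has no edges, because an empty interactome supports no
    analysis at all.
    """
    g = nx.Graph()
    n_sources = 0
    for records in edge_sets:
        n_sources += 1
        before = g.number_of_edges()
        n_in = 0
        for rec in records:
            n_in += 1
            if rec.id_a == rec.id_b:
                # parse layer already drops self-pairs; guard stays for
                # programmatically constructed records
                continue
            g.add_edge(rec.id_a, rec.id_b)
        logger.info(
            "[interactome] source %d: %d records, %d new edges",
            n_sources, n_in, g.number_of_edges() - before,
        )
    if n_sources == 0 or g.number_of_edges() == 0:
        raise ValueError("no edges supplied: cannot build an empty interactome")
    logger.info(
        "[interactome] merged network: %d nodes, %d interactions",
        g.number_of_nodes(), g.number_of_edges(),
    )
    return Interactome(g)


def degree(net: Interactome, node: str) -> int:
    """Number of distinct interaction partners of ``node``."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} is not in the interactome")
    return net.graph.degree(node)


def induced_subgraph(net: Interactome, nodes: Iterable[str]) -> Interactome:
    """Subgraph on ``nodes`` with all and only the edges among them.

    Nodes absent from the interactome are ignored with a warning.
    """
    nodes = set(nodes)
    missing = nodes - set(net.graph.nodes)
    if missing:
        logger.warning(
            "[interactome] induced_subgraph: ignoring %d unknown node(s)", len(missing)
        )
    sub = net.graph.subgraph(nodes - missing).copy()
    return Interactome(sub)
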