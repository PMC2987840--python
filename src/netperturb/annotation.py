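"""GO biological-process annotation of interactome nodes.

A protein directly annotated with a GO term implicitly carries every
ancestor of that term (the true-path rule): if a protein performs
"induction of apoptosis by intracellular signals" it also performs
"apoptosis" and "cell death". :func:`propagate_ancestors` makes this closure
explicit so that every term's annotated node set is complete and consistent
before sub-networks are extracted.

Ancestors are taken over ``is_a`` and ``part_of`` links within the
biological_process namespace; other relationship types (``regulates``,
``occurs_in``) do not imply annotation transfer and are ignored. ``part_of``
propagation can be switched off for strict is_a-only closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable

from .interactome import Interactome

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import RawAnnotation

logger = logging.getLogger(__name__)

__all__ = ["Ontology", "AnnotationMap", "propagate_ancestors", "annotated_fraction"]


@dataclass
class Ontology:
    """A biological_process term set with is_a / part_of parent links.

    ``parents`` maps each term to its direct parents; the transitive closure
    is computed on demand by :meth:`ancestors`. The parent relation must be
    acyclic (GO is a DAG); a cycle is reported as an error when closure is
    attempted.
    """

    names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    #: direct parents reached only via part_of (subset bookkeeping so the
    #: part_of switch can exclude them)
    part_of_parents: dict[str, set[str]] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.names)

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def name(self, term: str) -> str:
        return self.names.get(term, "")

    def ancestors(self, term: str, include_part_of: bool = True) -> set[str]:
        """All ancestors of ``term`` (excluding the term itself).

        Iterative DFS with an on-path marker so that a cycle in the parent
        relation raises instead of looping forever.
        """
        result: set[str] = set()
        on_path: list[str] = []
        on_path_set: set[str] = set()
        done: set[str] = set()

        def direct_parents(t: str) -> set[str]:
            ps = self.parents.get(t, set())
            if not include_part_of:
                ps = ps - self.part_of_parents.get(t, set())
            return ps

        stack: list[tuple[str, Iterable[str]]] = [(term, iter(sorted(direct_parents(term))))]
        on_path.append(term)
        on_path_set.add(term)
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p in on_path_set:
                    cycle = on_path[on_path.index(p):] + [p]
                    raise ValueError(f"cycle in ontology parent relation: {' -> '.join(cycle)}")
                if p in done:
                    result.add(p)
                    continue
                result.add(p)
                stack.append((p, iter(sorted(direct_parents(p)))))
                on_path.append(p)
                on_path_set.add(p)
                advanced = True
                break
            if not advanced:
                stack.pop()
                on_path.pop()
                on_path_set.discard(node)
                done.add(node)
        return result


@dataclass
class AnnotationMap:
    """Term → annotated interactome nodes, closed under ancestors.

    ``by_term`` and ``by_node`` are exact inverses; every node appearing in
    either is an interactome node. ``term_names`` carries display names
    through to the results table.
    """

    by_term: dict[str, set[str]] = field(default_factory=dict)
    by_node: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.by_term)

    def nodes_for(self, term: str) -> set[str]:
        if term not in self.by_term:
            raise KeyError(f"term {term!r} has no annotations")
        return self.by_term[term]

    def check_inverse(self) -> None:
        """Assert that by_term and by_node encode the same relation."""
        pairs_t = {(t, n) for t, ns in self.by_term.items() for n in ns}
        pairs_n = {(t, n) for n, ts in self.by_node.items() for t in ts}
        if pairs_t != pairs_n:
            raise AssertionError("by_term and by_node are not inverses")


def _invert(by_term: dict[str, set[str]]) -> dict[str, set[str]]:
    by_node: dict[str, set[str]] = {}
    for term, nodes in by_term.items():
        for n in nodes:
            by_node.setdefault(n, set()).add(term)
    return by_node


def propagate_ancestors(
    raw: Iterable["RawAnnotation"],
    ont: Ontology,
    net: Interactome,
    include_part_of: bool = True,
) -> AnnotationMap:
    """Attach annotations to interactome nodes with full ancestor closure.

    Raw annotations to proteins outside the interactome or to terms outside
    the ontology are dropped (with logged counts); every kept annotation is
    augmented with all its ancestors. Propagating an already-closed map
    again changes nothing (idempotence).
    """
    net_nodes = net.nodes
    by_term: dict[str, set[str]] = {}
    n_kept = n_unknown_node = n_unknown_term = 0

    @lru_cache(maxsize=None)
    def closure(term: str) -> frozenset[str]:
        return frozenset(ont.ancestors(term, include_part_of=include_part_of)) | {term}

    for ann in raw:
        if ann.protein_id not in net_nodes:
            n_unknown_node += 1
            continue
        if ann.term_id not in ont:
            n_unknown_term += 1
            continue
        n_kept += 1
        for t in closure(ann.term_id):
            by_term.setdefault(t, set()).add(ann.protein_id)

    if n_unknown_node or n_unknown_term:
        logger.info(
            "[annotation] dropped %d annotation(s) to non-interactome proteins, "
            "%d to unknown terms", n_unknown_node, n_unknown_term,
        )
    logger.info(
        "[annotation] %d direct annotations propagated to %d terms",
        n_kept, len(by_term),
    )
    names = {t: ont.name(t) for t in by_term}
    return AnnotationMap(by_term=by_term, by_node=_invert(by_term), term_names=names)


def annotated_fraction(am: AnnotationMap, net: Interactome) -> float:
    """Fraction of interactome nodes carrying at least one term."""
    if net.n_nodes == 0:
        raise ValueError("annotated_fraction of an empty interactome is undefined")
    annotated = set(am.by_node) & net.nodes
    return len(annotated) / net.n_nodes
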