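"""Randomized interactome instances and max-score empirical p-values.

The null model randomizes both layers the method depends on: topology and
annotation. Topology is randomized by degree-preserving rewiring — every
node keeps its exact number of interaction partners, so hubs stay hubs and
only *who* interacts with whom is destroyed. Annotation is randomized by
reassigning each term to the same number of nodes, drawn uniformly, so term
sizes are preserved while term-topology association is destroyed.

Scoring each random instance and recording its single best sub-network
score yields a max-score null: the empirical p-value of an observed score s
is the fraction of random instances whose best sub-network reaches s. Using
the per-instance maximum makes the p-value family-wise by construction —
no further multiple-testing correction over terms is applied.

Instances are pure functions of (inputs, instance seed); instance seeds are
derived from the master seed by index, so any evaluation order or scheduler
produces identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .affinity import TargetProfile
from .annotation import AnnotationMap
from .interactome import Interactome
from .io_formats import format_empirical_p
from .scoring import ScoreResult, score_all

logger = logging.getLogger(__name__)

__all__ = [
    "RandomizationResult",
    "rewire",
    "shuffle_annotations",
    "random_instance_max_score",
    "run_randomization",
    "empirical_pvalues",
]

#: attempted double-edge swaps per network edge; a common mixing heuristic
DEFAULT_SWAPS_PER_EDGE = 10

#: number of random interactome instances for the empirical null
DEFAULT_N_INSTANCES = 500


@dataclass
class RandomizationResult:
    """Max sub-network scores of N random interactome instances."""

    n_instances: int
    max_scores: list[float]
    master_seed: int

    def __post_init__(self) -> None:
        if len(self.max_scores) != self.n_instances:
            raise ValueError("need one max score per instance")

    @property
    def s_max_rand(self) -> float:
        """Highest score over all random instances."""
        return max(self.max_scores) if self.max_scores else 0.0


def _seed_seq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def instance_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-instance seed; independent of evaluation order."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def rewire(
    net: Interactome, seed, swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE
) -> Interactome:
    """Degree-preserving randomization by attempted double-edge swaps.

    Attempts ``swaps_per_edge · |E|`` swaps, each replacing edge pair
    (a–b, c–d) with (a–c, b–d); a swap is rejected when it would create a
    self-loop or a parallel edge. Every node's degree is exactly preserved.
    Deterministic given ``seed``. Graphs admitting no valid swap are
    returned unchanged with a warning.
    """
    if net.n_edges < 2:
        logger.warning("[randomization] fewer than 2 edges; rewiring is a no-op")
        return Interactome(net.graph.copy())
    rng = np.random.default_rng(_seed_seq(seed))
    edges = sorted(net.edges)  # canonical order → determinism
    m = len(edges)
    edge_set = set(edges)
    attempts = int(swaps_per_edge * m)
    ii = rng.integers(0, m, size=attempts)
    jj = rng.integers(0, m, size=attempts)
    flip = rng.integers(0, 2, size=attempts)
    n_success = 0
    for k in range(attempts):
        i, j = ii[k], jj[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[k]:
            c, d = d, c
        if a == c or b == d:  # would create a self-loop
            continue
        e1 = (a, c) if a <= c else (c, a)
        e2 = (b, d) if b <= d else (d, b)
        if e1 in edge_set or e2 in edge_set:  # would create a parallel edge
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        n_success += 1
    if n_success == 0:
        logger.warning("[randomization] no valid swap found; graph returned unchanged")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(edge_set)
    return Interactome(g)


def shuffle_annotations(
    am: AnnotationMap, net: Interactome, seed, candidates: str = "annotated"
) -> AnnotationMap:
    """Reassign each term to equally many uniformly drawn nodes.

    For every term with k annotated nodes, k nodes are sampled without
    replacement — independently across terms — from the nodes that carry at
    least one annotation (``candidates='annotated'``, the default) or from
    all interactome nodes (``candidates='all'``). The annotated pool is the
    default because function is only ever observed on annotated proteins;
    scattering terms onto never-annotated nodes (unannotated drug targets
    in particular) makes the null reflect the drug profile rather than the
    term-topology association under test. Per-term counts are exactly
    preserved either way. Ancestor closure is intentionally NOT re-imposed:
    the shuffle randomizes the term-node association as such.
    """
    if candidates == "all":
        pool = sorted(net.nodes)
    elif candidates == "annotated":
        pool = sorted(set(am.by_node) & net.nodes)
    else:
        raise ValueError(f"unknown candidate pool {candidates!r}")
    rng = np.random.default_rng(_seed_seq(seed))
    by_term: dict[str, set[str]] = {}
    for term in sorted(am.by_term):
        k = len(am.by_term[term])
        if k > len(pool):
            raise ValueError(
                f"term {term} annotates {k} nodes but only {len(pool)} candidates exist"
            )
        picks = rng.choice(len(pool), size=k, replace=False)
        by_term[term] = {pool[i] for i in picks}
    by_node: dict[str, set[str]] = {}
    for term, nodes in by_term.items():
        for n in nodes:
            by_node.setdefault(n, set()).add(term)
    return AnnotationMap(by_term=by_term, by_node=by_node, term_names=dict(am.term_names))


def random_instance_max_score(
    net: Interactome,
    am: AnnotationMap,
    profile: TargetProfile,
    seed,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    shuffle_candidates: str = "annotated",
    min_size: int = 1,
) -> float:
    """Best sub-network score of one randomized instance.

    Rewires the interactome and shuffles the annotation (seeds for both
    derived from the instance seed), scores every term, and returns the
    maximum s_net (0 when no network scores at all).
    """
    rewire_ss, shuffle_ss = _seed_seq(seed).spawn(2)
    rand_net = rewire(net, rewire_ss, swaps_per_edge=swaps_per_edge)
    rand_am = shuffle_annotations(am, rand_net, shuffle_ss, candidates=shuffle_candidates)
    results = score_all(rand_net, rand_am, profile, min_size=min_size)
    return max((r.s_net for r in results), default=0.0)


def run_randomization(
    net: Interactome,
    am: AnnotationMap,
    profile: TargetProfile,
    n_instances: int = DEFAULT_N_INSTANCES,
    master_seed: int = 0,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    shuffle_candidates: str = "annotated",
    min_size: int = 1,
) -> RandomizationResult:
    """Score ``n_instances`` independent random instances of the interactome."""
    max_scores: list[float] = []
    for i in range(n_instances):
        s = random_instance_max_score(
            net, am, profile, instance_seed(master_seed, i),
            swaps_per_edge=swaps_per_edge,
            shuffle_candidates=shuffle_candidates,
            min_size=min_size,
        )
        max_scores.append(s)
    rr = RandomizationResult(n_instances, max_scores, master_seed)
    logger.info(
        "[randomization] %d instances, s_max_rand = %.4g", n_instances, rr.s_max_rand
    )
    return rr


def empirical_pvalues(
    observed: list[ScoreResult], rr: RandomizationResult
) -> list[ScoreResult]:
    """Attach max-score empirical p-values to observed results.

    p = |{instances whose best score ≥ s}| / N; zero exceedances reported
    as the bound "<1/N". p is a non-increasing step function of s.
    """
    if rr.n_instances < 1:
        raise ValueError("need at least one random instance")
    scores = np.asarray(rr.max_scores)
    out: list[ScoreResult] = []
    for r in observed:
        k = int(np.sum(scores >= r.s_net))
        out.append(
            replace(r, p_value=k / rr.n_instances,
                    p_value_text=format_empirical_p(k, rr.n_instances))
        )
    return out
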