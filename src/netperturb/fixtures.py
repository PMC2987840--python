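"""Synthetic benchmark generator with planted perturbation structure.

Real inputs for this method (a curated human interactome, the full GO
biological_process ontology, genome-wide annotations, a measured drug
profile) are large, versioned, and not redistributable in a test suite.
This module generates all four inputs with known planted structure instead:

* a background interaction network (Erdős–Rényi, or a configuration model
  for a prescribed degree sequence);
* one or more planted functional modules — connected, densely wired node
  sets annotated with their own term;
* a small but nontrivial ontology (depth 3: leaf terms under intermediate
  branch terms under the root, with one part_of link) plus decoy terms
  whose annotation counts match the planted module, so that recovering the
  planted term at rank 1 tests the mechanism and not term size;
* a drug target profile with targets in defined roles: direct (inside the
  module), peripheral (wired to a module member), chained (reaching the
  module only through other targets), and zero-affinity decoys scattered
  at random (competed counts ≥ uncompeted, as unspecific binders present).

Attached targets receive high peptide counts with near-complete
competition, concentrating the profile's affinity on the planted module.
Everything is deterministic given the master seed. The generator can also
write the four inputs in their standard on-disk formats, which doubles as a
round-trip test of the readers.

Default sizes model a small benchmark: a 500-protein network at Erdős–Rényi
edge probability 0.01 (mean degree ≈ 5, the order of curated interactomes),
one 40-protein module at internal density 0.3, 10 decoy terms and 5
high-affinity attached targets of which a chain of 2.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .affinity import TargetProfile, build_profile
from .annotation import AnnotationMap, Ontology, propagate_ancestors
from .interactome import Interactome
from .io_formats import ProfileRow, RawAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleSpec",
    "FixtureSpec",
    "FixtureBundle",
    "generate_fixture",
    "write_fixture_files",
    "counts_from_affinity",
]

ROOT_TERM = "GO:0000001"
PLANTED_BRANCH = "GO:0000900"
DECOY_BRANCH = "GO:0000901"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted functional module: node count and internal edge density."""

    size: int
    density: float = 0.3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance."""

    n_nodes: int = 500
    er_p: float = 0.01
    degree_sequence: tuple[int, ...] | None = None  # overrides er_p when set
    modules: tuple[ModuleSpec, ...] = (ModuleSpec(size=40, density=0.3),)
    n_decoy_terms: int = 10
    n_direct: int = 0
    n_peripheral: int = 3
    chain_length: int = 2
    n_decoy_targets: int = 5
    attached_p_t: int = 100  # uncompeted peptide count of attached targets
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        for m in self.modules:
            if m.size > self.n_nodes:
                raise ValueError(
                    f"module of size {m.size} does not fit in {self.n_nodes} nodes"
                )
            if not (0.0 <= m.density <= 1.0):
                raise ValueError("module density must be in [0, 1]")
        if sum(m.size for m in self.modules) > self.n_nodes:
            raise ValueError("planted modules exceed the node budget")
        negatives = [
            v for v in (self.n_decoy_terms, self.n_direct, self.n_peripheral,
                        self.chain_length, self.n_decoy_targets)
            if v < 0
        ]
        if negatives:
            raise ValueError("all fixture counts must be non-negative")
        if self.modules and self.n_direct > min(m.size for m in self.modules):
            raise ValueError("more direct targets than module members")


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture, for recovery tests."""

    planted_terms: list[str]
    module_nodes: dict[str, list[str]]  # term -> members
    target_roles: dict[str, str]  # protein -> direct|peripheral|chained|decoy
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class FixtureBundle:
    """A complete generated input set plus its ground truth."""

    net: Interactome
    ontology: Ontology
    annotations: AnnotationMap
    raw_annotations: list[RawAnnotation]
    profile: TargetProfile
    profile_rows: list[ProfileRow]
    truth: FixtureTruth
    spec: FixtureSpec = field(repr=False, default=None)


def counts_from_affinity(a_target: float, p_t: int) -> tuple[int, int]:
    """Peptide counts (p_t, p_comp) whose affinity score is ≈ ``a_target``.

    Inverts a_t = (1 − p_comp/p_t)·log10(p_t) with integer rounding of
    p_comp; re-applying the affinity formula recovers the requested value
    within log10(p_t)/(2·p_t) (half a count step). Values above log10(p_t)
    are unreachable at this p_t and rejected.
    """
    if p_t < 1:
        raise ValueError("p_t must be a positive peptide count")
    cap = math.log10(p_t)
    if a_target < 0 or a_target > cap:
        raise ValueError(f"affinity {a_target} unreachable with p_t={p_t} (max {cap:g})")
    if cap == 0.0:  # p_t = 1: only a = 0 is representable
        return p_t, p_t
    p_comp = round(p_t * (1.0 - a_target / cap))
    return p_t, p_comp


# ---------------------------------------------------------------------------
# generation internals

def _node_name(i: int) -> str:
    return f"P{i:04d}"


def _background_graph(spec: FixtureSpec, rng: np.random.Generator) -> nx.Graph:
    if spec.degree_sequence is not None:
        seq = list(spec.degree_sequence)
        if sum(seq) % 2:
            seq[0] += 1  # configuration model needs an even stub count
        mg = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
        g = nx.Graph(mg)
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        g = nx.gnp_random_graph(spec.n_nodes, spec.er_p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})


def _wire_module(g: nx.Graph, members: list[str], density: float,
                 rng: np.random.Generator) -> None:
    """Make ``members`` connected and internally wired at ``density``."""
    k = len(members)
    if k < 2:
        return
    order = list(members)
    rng.shuffle(order)
    for i in range(1, k):  # random recursive tree → connected
        g.add_edge(order[i], order[int(rng.integers(0, i))])
    target_edges = int(round(density * k * (k - 1) / 2))
    internal = {frozenset(e) for e in g.subgraph(members).edges}
    guard = 0
    while len(internal) < target_edges and guard < 50 * target_edges:
        guard += 1
        a, b = rng.choice(k, size=2, replace=False)
        e = frozenset((members[a], members[b]))
        if e not in internal:
            internal.add(e)
            g.add_edge(*tuple(e))


def _build_ontology(planted_terms: list[str], decoy_terms: list[str]) -> Ontology:
    ont = Ontology()
    ont.names[ROOT_TERM] = "biological process root"
    ont.parents[ROOT_TERM] = set()
    ont.part_of_parents[ROOT_TERM] = set()
    ont.names[PLANTED_BRANCH] = "planted branch"
    ont.parents[PLANTED_BRANCH] = {ROOT_TERM}
    ont.part_of_parents[PLANTED_BRANCH] = set()
    ont.names[DECOY_BRANCH] = "decoy branch"
    # one part_of link so propagation over part_of is exercised
    ont.parents[DECOY_BRANCH] = {ROOT_TERM}
    ont.part_of_parents[DECOY_BRANCH] = {ROOT_TERM}
    for i, t in enumerate(planted_terms, start=1):
        ont.names[t] = f"planted process {i}"
        ont.parents[t] = {PLANTED_BRANCH}
        ont.part_of_parents[t] = set()
    for i, t in enumerate(decoy_terms, start=1):
        ont.names[t] = f"decoy process {i}"
        ont.parents[t] = {DECOY_BRANCH}
        ont.part_of_parents[t] = set()
    return ont


def _sample(pool: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    if k > len(pool):
        raise ValueError(f"cannot sample {k} nodes from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate a full synthetic input set from ``spec``.

    Deterministic given ``spec.seed``. Raises on infeasible specs (modules
    larger than the graph, more samples than candidates).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = _background_graph(spec, rng)
    all_nodes = sorted(g.nodes)

    # planted modules: disjoint connected node sets, one term each
    planted_terms = [f"GO:{2 + i:07d}" for i in range(len(spec.modules))]
    module_nodes: dict[str, list[str]] = {}
    used: set[str] = set()
    for term, mspec in zip(planted_terms, spec.modules):
        pool = [n for n in all_nodes if n not in used]
        members = _sample(pool, mspec.size, rng)
        used.update(members)
        _wire_module(g, members, mspec.density, rng)
        module_nodes[term] = members

    first_module = module_nodes[planted_terms[0]] if planted_terms else []

    # targets in defined roles. Attached (peripheral/chained) targets keep
    # exactly their role-defining interactions: stray background edges are
    # removed so that a "chained" target really reaches the module only
    # through the preceding target and the truth-record roles are exact.
    target_roles: dict[str, str] = {}
    for n in _sample(first_module, spec.n_direct, rng) if first_module else []:
        target_roles[n] = "direct"

    def background_pool() -> list[str]:
        return [n for n in all_nodes if n not in used and n not in target_roles]

    def attach(n: str, anchor_pool: list[str]) -> None:
        g.remove_edges_from(list(g.edges(n)))
        if anchor_pool:
            g.add_edge(n, anchor_pool[int(rng.integers(0, len(anchor_pool)))])

    for n in _sample(background_pool(), spec.n_peripheral, rng):
        target_roles[n] = "peripheral"
        attach(n, first_module)

    prev: str | None = None
    for n in _sample(background_pool(), spec.chain_length, rng):
        target_roles[n] = "chained"
        attach(n, first_module if prev is None else [prev])
        prev = n

    # zero-interaction proteins can never join a sub-network; drop them now
    g.remove_nodes_from(list(nx.isolates(g)))
    all_nodes = sorted(g.nodes)

    for n in _sample([n for n in all_nodes if n not in used and n not in target_roles],
                     spec.n_decoy_targets, rng):
        target_roles[n] = "decoy"

    # decoy terms: annotation counts matched to the first planted module;
    # annotated to background nodes (never to profiled targets — a decoy
    # term must not inherit the drug's affinity by construction)
    decoy_terms = [f"GO:{100 + i:07d}" for i in range(spec.n_decoy_terms)]
    decoy_size = len(first_module) if first_module else max(1, spec.n_nodes // 10)
    non_module = [n for n in all_nodes if n not in used and n not in target_roles]
    raw: list[RawAnnotation] = []
    for term, members in module_nodes.items():
        raw.extend(RawAnnotation(n, term) for n in members)
    for term in decoy_terms:
        for n in _sample(non_module, decoy_size, rng):
            raw.append(RawAnnotation(n, term))

    ontology = _build_ontology(planted_terms, decoy_terms)
    net = Interactome(g)
    am = propagate_ancestors(raw, ontology, net)

    # profile rows: attached targets high-affinity & near-fully competed,
    # decoys with competed counts at or above uncompeted (a_t = 0)
    rows: list[ProfileRow] = []
    for n in sorted(target_roles):
        role = target_roles[n]
        if role == "decoy":
            p_t = int(rng.integers(3, 20))
            p_comp = p_t + int(rng.integers(0, 4))
        else:
            p_t = spec.attached_p_t + int(rng.integers(-20, 21))
            p_comp = int(rng.integers(0, 5))
        rows.append(ProfileRow(n, p_t=p_t, p_comp=p_comp))
    profile = build_profile(rows) if rows else None

    truth = FixtureTruth(
        planted_terms=planted_terms,
        module_nodes=module_nodes,
        target_roles=target_roles,
        seed=spec.seed,
    )
    logger.info(
        "[fixtures] generated %d-node network, %d terms, %d targets (seed %d)",
        net.n_nodes, len(ontology.names), len(rows), spec.seed,
    )
    return FixtureBundle(net, ontology, am, raw, profile, rows, truth, spec)


# ---------------------------------------------------------------------------
# on-disk round trip

def _write_obo(ont: Ontology, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\ndefault-namespace: biological_process\n")
        for term in sorted(ont.names):
            fh.write(f"\n[Term]\nid: {term}\nname: {ont.names[term]}\n")
            fh.write("namespace: biological_process\n")
            for p in sorted(ont.parents.get(term, set())):
                if p in ont.part_of_parents.get(term, set()):
                    fh.write(f"relationship: part_of {p}\n")
                else:
                    fh.write(f"is_a: {p}\n")


def write_fixture_files(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four inputs in their standard formats plus the truth file.

    Returns ``{"edges": ..., "obo": ..., "annotations": ..., "profile": ...,
    "truth": ...}``. Reading the files back through :mod:`io_formats`
    reproduces the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "profile": outdir / "profile.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in sorted(bundle.net.edges):
            fh.write(f"{a}\t{b}\n")
    _write_obo(bundle.ontology, paths["obo"])
    with open(paths["annotations"], "w") as fh:
        fh.write("protein_id\tterm_id\n")
        for ann in sorted(set(bundle.raw_annotations),
                          key=lambda a: (a.protein_id, a.term_id)):
            fh.write(f"{ann.protein_id}\t{ann.term_id}\n")
    with open(paths["profile"], "w") as fh:
        fh.write("protein_id\tp_t\tp_comp\n")
        for r in bundle.profile_rows:
            fh.write(f"{r.protein_id}\t{r.p_t}\t{r.p_comp}\n")
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    return paths
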