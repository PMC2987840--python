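"""Readers and writers for every external format the tool touches.

Inputs: plain TSV edge lists or PSI-MI TAB 2.5 interaction files, OBO
ontologies, GAF 2.x or two-column TSV annotation tables, and TSV drug
target profiles. Outputs: the ranked score table (TSV) and Cytoscape-ready
network exports (GraphML, or SIF plus a node-attribute table).

All downstream modules consume only the domain types produced here
(:class:`EdgeRecord`, :class:`RawAnnotation`, :class:`ProfileRow`) or in
:mod:`netperturb.annotation` (:class:`~netperturb.annotation.Ontology`).

A note on identifiers, stated loudly because it bites: this tool performs
NO identifier mapping. Edge lists, annotations and the target profile must
all use one identifier namespace (all UniProt accessions, or all gene
symbols, ...). Mixed namespaces silently produce empty intersections.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import obonet

from .annotation import Ontology

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ScoreResult
    from .subnetworks import PerturbedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "RawAnnotation",
    "ProfileRow",
    "read_edge_list",
    "read_obo",
    "read_annotations",
    "read_target_profile",
    "write_score_table",
    "export_network",
    "import_network",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class EdgeRecord:
    """One undirected protein-protein interaction; (a,b) ≡ (b,a)."""

    id_a: str
    id_b: str

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("edge endpoints must be non-empty strings")

    def canonical(self) -> tuple[str, str]:
        a, b = self.id_a, self.id_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RawAnnotation:
    """One direct protein → GO term association, before propagation."""

    protein_id: str
    term_id: str


@dataclass(frozen=True)
class ProfileRow:
    """One drug target profile entry.

    Either competition-count mode (``p_t`` set, ``p_comp`` optionally set)
    or external-weight mode (``external_weight`` set); never both.
    """

    protein_id: str
    p_t: int | None = None
    p_comp: int | None = None
    external_weight: float | None = None

    def __post_init__(self) -> None:
        count_mode = self.p_t is not None
        weight_mode = self.external_weight is not None
        if count_mode == weight_mode:
            raise ValueError(
                f"profile row {self.protein_id!r}: exactly one of peptide counts "
                "or external weight must be given"
            )


# ---------------------------------------------------------------------------
# edge lists

_HEADER_TOKENS = {
    "id_a", "id_b", "protein_a", "protein_b", "source", "target",
    "interactor_a", "interactor_b", "node1", "node2", "from", "to",
    "protein1", "protein2", "gene_a", "gene_b",
}


def _mitab_id(field: str, path: str, lineno: int) -> str:
    """First identifier of a PSI-MI TAB field like ``uniprotkb:P00519``."""
    first = field.split("|")[0].strip()
    if not first or first == "-":
        raise ValueError(f"{path}:{lineno}: empty interactor identifier")
    if ":" in first:
        first = first.split(":", 1)[1]
    # strip surrounding quotes some exports add
    return first.strip('"')


def read_edge_list(path: str | Path, fmt: str = "tsv") -> list[EdgeRecord]:
    """Parse an interaction file into edge records.

    ``fmt='tsv'``: two tab-separated identifier columns (extra columns
    ignored); comment lines (leading ``#``) and one optional recognizable
    header line are skipped. ``fmt='psimitab'``: PSI-MI TAB 2.5, identifier
    pairs taken from the first two columns.

    Self-pairs are dropped with a logged count — a self-interaction can
    never link a target to a sub-network and would break degree-preserving
    rewiring. Duplicate pairs are preserved (deduplication happens when the
    interactome is built).
    """
    if fmt not in ("tsv", "psimitab"):
        raise ValueError(f"unsupported edge list format {fmt!r}")
    path = Path(path)
    records: list[EdgeRecord] = []
    n_self = 0
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            if fmt == "tsv":
                if first_data_line and {f.strip().lower() for f in fields[:2]} <= _HEADER_TOKENS:
                    first_data_line = False
                    continue
                first_data_line = False
                a, b = fields[0].strip(), fields[1].strip()
                if not a or not b:
                    raise ValueError(f"{path}:{lineno}: empty identifier")
            else:
                a = _mitab_id(fields[0], str(path), lineno)
                b = _mitab_id(fields[1], str(path), lineno)
            if a == b:
                n_self += 1
                continue
            records.append(EdgeRecord(a, b))
    if n_self:
        logger.info("[io] %s: dropped %d self-pair(s)", path.name, n_self)
    if not records:
        logger.warning("[io] %s: no interactions parsed", path.name)
    return records


# ---------------------------------------------------------------------------
# ontology

def read_obo(path: str | Path) -> Ontology:
    """Load an OBO ontology, restricted to biological_process.

    Keeps ``is_a`` and ``part_of`` parent links between retained terms;
    obsolete terms are excluded; other relationship types are ignored with a
    warning. Terms without an explicit namespace inherit the file's
    ``default-namespace`` header.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete terms
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: no [Term] stanzas found")

    default_ns = graph.graph.get("default-namespace", [""])
    if isinstance(default_ns, (list, tuple)):
        default_ns = default_ns[0] if default_ns else ""

    def namespace(term: str) -> str:
        return graph.nodes[term].get("namespace", default_ns)

    bp_terms = {t for t in graph.nodes if namespace(t) == "biological_process"}
    ont = Ontology()
    ignored_rels: set[str] = set()
    for term in bp_terms:
        ont.names[term] = graph.nodes[term].get("name", "")
        ont.parents.setdefault(term, set())
        ont.part_of_parents.setdefault(term, set())
        # obonet stores child -> parent edges keyed by relationship type
        for _, parent, rel in graph.out_edges(term, keys=True):
            if rel not in ("is_a", "part_of"):
                ignored_rels.add(rel)
                continue
            if parent not in bp_terms:
                continue
            ont.parents[term].add(parent)
            if rel == "part_of":
                ont.part_of_parents[term].add(parent)
    if ignored_rels:
        logger.warning(
            "[io] %s: ignoring relationship type(s): %s",
            Path(path).name, ", ".join(sorted(ignored_rels)),
        )
    logger.info(
        "[io] %s: %d biological_process terms", Path(path).name, len(ont.names)
    )
    return ont


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path: str | Path, fmt: str = "tsv") -> list[RawAnnotation]:
    """Parse protein → GO term associations.

    ``fmt='tsv'``: two columns (protein, term). ``fmt='gaf'``: GAF 2.x;
    only aspect ``P`` (biological_process) rows are kept, and rows whose
    qualifier contains ``NOT`` are skipped with a logged count. Duplicates
    are preserved; deduplication happens during propagation.
    """
    if fmt not in ("tsv", "gaf"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    path = Path(path)
    out: list[RawAnnotation] = []
    n_not = 0
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if fmt == "gaf":
                if line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GAF row has fewer than 9 columns")
                qualifier, go_id, aspect = fields[3], fields[4], fields[8]
                if "NOT" in qualifier.split("|"):
                    n_not += 1
                    continue
                if aspect != "P":
                    continue
                out.append(RawAnnotation(fields[1], go_id))
            else:
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                prot, term = fields[0].strip(), fields[1].strip()
                if first_data_line and term.strip().lower() in ("term_id", "go_id", "term"):
                    first_data_line = False
                    continue
                first_data_line = False
                out.append(RawAnnotation(prot, term))
    if n_not:
        logger.info("[io] %s: skipped %d NOT-qualified row(s)", path.name, n_not)
    return out


# ---------------------------------------------------------------------------
# target profile

def read_target_profile(path: str | Path) -> list[ProfileRow]:
    """Parse a drug target profile TSV.

    Header row required. Count mode columns: ``protein_id``, ``p_t``,
    ``p_comp`` (``p_comp`` cells may be empty → treated downstream as fully
    competed). Weight mode columns: ``protein_id``, ``weight``. Mixing both
    modes, duplicate protein identifiers and negative counts are errors.
    """
    path = Path(path)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty profile file")
        cols = [c.strip().lower() for c in reader.fieldnames]
        rows = list(reader)
    if "protein_id" not in cols:
        raise ValueError(f"{path}: missing 'protein_id' column")
    has_counts = "p_t" in cols
    has_weight = "weight" in cols
    if has_counts and has_weight:
        raise ValueError(f"{path}: mixed modes — both peptide counts and weights present")
    if not has_counts and not has_weight:
        raise ValueError(f"{path}: need either p_t/p_comp columns or a weight column")

    def get(row: dict, key: str) -> str:
        for k, v in row.items():
            if k is not None and k.strip().lower() == key:
                return (v or "").strip()
        return ""

    out: list[ProfileRow] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        pid = get(row, "protein_id")
        if not pid:
            raise ValueError(f"{path}:{i}: empty protein_id")
        if pid in seen:
            raise ValueError(f"{path}:{i}: duplicate protein_id {pid!r}")
        seen.add(pid)
        if has_counts:
            p_t = int(get(row, "p_t"))
            if p_t < 0:
                raise ValueError(f"{path}:{i}: negative peptide count")
            p_comp_s = get(row, "p_comp")
            p_comp = int(p_comp_s) if p_comp_s else None
            if p_comp is not None and p_comp < 0:
                raise ValueError(f"{path}:{i}: negative peptide count")
            out.append(ProfileRow(pid, p_t=p_t, p_comp=p_comp))
        else:
            out.append(ProfileRow(pid, external_weight=float(get(row, "weight"))))
    return out


# ---------------------------------------------------------------------------
# score table

SCORE_COLUMNS = [
    "rank", "term_id", "term_name", "component_index", "n_net", "n_annot",
    "n_drug", "n_competed", "s_net", "p_value_text",
]


def format_empirical_p(n_exceed: int, n_instances: int) -> str:
    """Empirical p-value text: ``k/N``, or the bound ``<1/N`` at zero count.

    With no random instance reaching the observed score the p-value is only
    bounded, not estimated; at N=500 zero exceedances prints ``<0.002``.
    """
    if n_instances < 1:
        raise ValueError("need at least one random instance")
    if n_exceed == 0:
        return f"<{1 / n_instances:g}"
    return f"{n_exceed / n_instances:g}"


def write_score_table(results: Sequence["ScoreResult"], path: str | Path) -> None:
    """Write the ranked results table as TSV (header always written)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORE_COLUMNS)
        for r in results:
            writer.writerow([
                r.rank, r.term, r.term_name, r.component_index, r.n_net,
                r.n_annot_net, r.n_drug_net, r.n_competed,
                f"{r.s_net:.6g}", r.p_value_text or "",
            ])
    logger.info("[io] wrote %d result row(s) to %s", len(results), path)


# ---------------------------------------------------------------------------
# network export (Cytoscape-ready)

def _as_attr_graph(
    net: "PerturbedNetwork",
    affinities: dict[str, float] | None = None,
    node_attrs: dict[str, dict[str, object]] | None = None,
) -> nx.Graph:
    g = nx.Graph()
    affinities = affinities or {}
    all_nodes = net.annotated_members | net.target_members
    for n in sorted(all_nodes):
        attrs: dict[str, object] = {
            "is_target": n in net.target_members,
            "is_annotated": n in net.annotated_members,
            "affinity": float(affinities.get(n, 0.0)),
        }
        if node_attrs and n in node_attrs:
            attrs.update(node_attrs[n])
        g.add_node(n, **attrs)
    g.add_edges_from(net.edges)
    return g


def export_network(
    net: "PerturbedNetwork",
    path: str | Path,
    fmt: str = "graphml",
    affinities: dict[str, float] | None = None,
    node_attrs: dict[str, dict[str, object]] | None = None,
) -> list[Path]:
    """Export a perturbed sub-network for visualization.

    ``graphml`` is the lossless default; ``sif`` writes a Cytoscape SIF
    file plus a node-attribute TSV next to it (``<path>.nodes.tsv``).
    Node attributes: ``is_target``, ``is_annotated``, ``affinity``, plus any
    passthrough attributes (e.g. ``is_kinase``) given in ``node_attrs``.
    Returns the list of files written.
    """
    path = Path(path)
    g = _as_attr_graph(net, affinities, node_attrs)
    if g.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return [path]
    if fmt == "sif":
        with open(path, "w") as fh:
            isolated = set(g.nodes)
            for a, b in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{a}\tpp\t{b}\n")
                isolated.discard(a)
                isolated.discard(b)
            for n in sorted(isolated):
                fh.write(f"{n}\n")
        attr_path = path.with_name(path.name + ".nodes.tsv")
        keys = sorted({k for _, d in g.nodes(data=True) for k in d})
        with open(attr_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["node"] + keys)
            for n in sorted(g.nodes):
                writer.writerow([n] + [g.nodes[n].get(k, "") for k in keys])
        return [path, attr_path]
    raise ValueError(f"unsupported export format {fmt!r}")


def _parse_attr(value: str) -> object:
    if value in ("True", "False"):
        return value == "True"
    try:
        f = float(value)
    except ValueError:
        return value
    return int(f) if f.is_integer() and "." not in value and "e" not in value.lower() else f


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Re-read an exported network; inverse of :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 3:
                    g.add_edge(fields[0], fields[2])
                elif fields[0]:
                    g.add_node(fields[0])
        attr_path = path.with_name(path.name + ".nodes.tsv")
        if attr_path.exists():
            with open(attr_path) as fh:
                reader = csv.DictReader(fh, delimiter="\t")
                for row in reader:
                    node = row.pop("node")
                    if node in g:
                        g.nodes[node].update({k: _parse_attr(v) for k, v in row.items()})
        return g
    raise ValueError(f"unsupported import format {fmt!r}")
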