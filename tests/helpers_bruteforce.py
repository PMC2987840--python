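"""Independent brute-force oracle for sub-network extraction and scoring.

Deliberately avoids the package's own machinery: target attachment is
decided by exhaustive simple-path enumeration (a target is attached iff
some path to an annotated member has only targets in its interior), and
connected components are found with a hand-rolled union-find. Only feasible
on tiny graphs; used to validate the production implementation exactly.
"""

from __future__ import annotations

import networkx as nx


def _union_find_components(nodes: set[str], graph: nx.Graph) -> list[set[str]]:
    parent = {v: v for v in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in graph.edges:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return sorted(comps.values(), key=min)


def oracle_attached_targets(
    graph: nx.Graph, members: set[str], targets: set[str]
) -> set[str]:
    """Targets linked to members directly or via target-only interiors.

    Pure path enumeration over all simple paths — exponential, tiny graphs
    only.
    """
    attached = set()
    for t in targets & set(graph):
        if t in members:
            attached.add(t)
            continue
        for m in members:
            if m not in graph or not nx.has_path(graph, t, m):
                continue
            for path in nx.all_simple_paths(graph, t, m):
                if all(x in targets for x in path[1:-1]):
                    attached.add(t)
                    break
            if t in attached:
                break
    return attached


def oracle_score_all(
    graph: nx.Graph,
    annotations: dict[str, set[str]],
    profile,
    include_zero: bool = True,
) -> list[tuple]:
    """Direct evaluation of the perturbation score over every term.

    Returns rows (rank, term, component_index, n_net, n_annot, n_drug,
    t_drug_net, s_net) sorted exactly like the production ranking
    (descending score, term accession, component index).
    """
    affinities = {t.protein_id: t.a_t for t in profile.targets}
    t_drug = profile.t_drug
    node_set = set(graph)
    target_set = set(affinities)
    rows = []
    for term in sorted(annotations):
        members = set(annotations[term]) & node_set
        if not members:
            continue
        attached = oracle_attached_targets(graph, members, target_set & node_set)
        universe = members | attached
        for idx, comp in enumerate(_union_find_components(universe, graph)):
            n_net = len(comp)
            n_annot = len(comp & members)
            n_drug = len(comp & attached)
            t_net = sum(affinities[t] for t in sorted(comp & attached))
            if t_drug > 0:
                s = (n_annot / n_net) * (n_drug / n_net) * (t_net / t_drug)
            else:
                s = 0.0
            if s > 0 or include_zero:
                rows.append((term, idx, n_net, n_annot, n_drug, t_net, s))
    rows.sort(key=lambda r: (-r[6], r[0], r[1]))
    return [(rank, *row) for rank, row in enumerate(rows, start=1)]
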