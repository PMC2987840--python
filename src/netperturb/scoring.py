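"""The perturbation score s_net and ranked scoring of all terms.

Each perturbed functional sub-network is scored by the product of three
ratios:

    s_net = (n_annot,net / n_net) · (n_drug,net / n_net) · (T_drug,net / T_drug)

* annotation purity — the fraction of the network's nodes that actually
  carry the function; peripheral targets dilute it;
* target density — the drug's impact relative to network size; generic
  functions produce huge sub-networks in which a handful of targets no
  longer matters, and a drug should hit a function at several points;
* captured affinity — the share of the drug's total binding affinity
  (Σ a_t over ALL profiled targets, in-network or not) that falls inside
  this network; strong targets count more than weak or uncompeted ones.

Each factor lies in [0, 1], so s_net does too; s_net is 0 exactly when the
network contains no target or no binding affinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .affinity import TargetProfile
from .annotation import AnnotationMap
from .interactome import Interactome
from .subnetworks import PerturbedNetwork, build_perturbed_networks

logger = logging.getLogger(__name__)

__all__ = ["ScoreResult", "score_network", "score_all", "rank_results"]


@dataclass(frozen=True)
class ScoreResult:
    """One row of the output table: a scored perturbed sub-network."""

    term: str
    term_name: str
    component_index: int
    n_net: int
    n_annot_net: int
    n_drug_net: int
    n_competed: int
    t_drug_net: float
    s_net: float
    p_value: float | None = None
    p_value_text: str = ""
    rank: int | None = None


def score_network(
    pnet: PerturbedNetwork, profile: TargetProfile, term_name: str = ""
) -> ScoreResult:
    """Score one perturbed sub-network (p-value and rank left unset)."""
    if profile.t_drug <= 0:
        raise ValueError("profile has no binding affinity (T_drug = 0); nothing to score")
    affinities = profile.affinities
    in_net = sorted(pnet.target_members)
    t_drug_net = sum(affinities[t] for t in in_net)
    n_competed = sum(1 for t in in_net if affinities[t] > 0)
    s_net = (
        (pnet.n_annot_net / pnet.n_net)
        * (pnet.n_drug_net / pnet.n_net)
        * (t_drug_net / profile.t_drug)
    )
    return ScoreResult(
        term=pnet.term,
        term_name=term_name,
        component_index=pnet.component_index,
        n_net=pnet.n_net,
        n_annot_net=pnet.n_annot_net,
        n_drug_net=pnet.n_drug_net,
        n_competed=n_competed,
        t_drug_net=t_drug_net,
        s_net=s_net,
    )


def rank_results(results: list[ScoreResult], collapse: bool = False) -> list[ScoreResult]:
    """Sort by descending score and assign ranks 1..n.

    Ties break by term accession ascending, then component index. With
    ``collapse``, only each term's best component is kept (Table-style
    one-row-per-function output).
    """
    if collapse:
        best: dict[str, ScoreResult] = {}
        for r in results:
            cur = best.get(r.term)
            if cur is None or (r.s_net, -r.component_index) > (cur.s_net, -cur.component_index):
                best[r.term] = r
        results = list(best.values())
    ordered = sorted(results, key=lambda r: (-r.s_net, r.term, r.component_index))
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


def score_all(
    net: Interactome,
    am: AnnotationMap,
    profile: TargetProfile,
    collapse: bool = False,
    include_zero: bool = False,
    min_size: int = 1,
) -> list[ScoreResult]:
    """Score every term's perturbed sub-networks and rank them.

    Every term with at least one annotated interactome node is processed.
    Networks with score 0 (no target, or no competed target) are suppressed
    unless ``include_zero`` is set; the reported table concerns perturbed
    networks only.
    """
    results: list[ScoreResult] = []
    for term in sorted(am.by_term):
        name = am.term_names.get(term, "")
        for pnet in build_perturbed_networks(net, am, term, profile, min_size=min_size):
            if profile.t_drug > 0:
                r = score_network(pnet, profile, term_name=name)
            else:
                # a profile with no binding affinity perturbs nothing
                r = ScoreResult(
                    term=pnet.term, term_name=name,
                    component_index=pnet.component_index, n_net=pnet.n_net,
                    n_annot_net=pnet.n_annot_net, n_drug_net=pnet.n_drug_net,
                    n_competed=0, t_drug_net=0.0, s_net=0.0,
                )
            if r.s_net > 0 or include_zero:
                results.append(r)
    ranked = rank_results(results, collapse=collapse)
    # debug level: this fires once per randomization instance
    logger.debug(
        "[scoring] %d sub-network(s) scored over %d term(s)%s",
        len(ranked), len(am.by_term), " (collapsed)" if collapse else "",
    )
    return ranked
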