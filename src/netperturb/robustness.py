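"""Rank-stability analyses: leave-one-out and hub weighting.

Two sanity checks on the ranking. Leave-one-out drops each profiled target
in turn, re-scores everything (with the affinity denominator T_drug
recomputed), and tracks how the ranks of selected terms move: high-affinity
targets should matter, weak or uncompeted binders should not. Hub weighting
multiplies (mode ``up``) or divides (mode ``down``) every target's affinity
by log10 of its interactome degree, probing whether the ranking is driven
by the targets' local topology rather than by the functions they hit; a
stable top of the table indicates the latter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .affinity import TargetProfile
from .annotation import AnnotationMap
from .interactome import Interactome
from .scoring import ScoreResult, score_all

logger = logging.getLogger(__name__)

__all__ = ["leave_one_out", "hub_weighting"]


def _rank_of(results: list[ScoreResult], term: str) -> float:
    """Rank of a term's best sub-network; NaN when absent from results."""
    ranks = [r.rank for r in results if r.term == term]
    return float(min(ranks)) if ranks else float("nan")


def leave_one_out(
    net: Interactome,
    am: AnnotationMap,
    profile: TargetProfile,
    tracked_terms: list[str],
    collapse: bool = True,
    min_size: int = 1,
) -> pd.DataFrame:
    """Rank matrix of tracked terms under single-target removal.

    One row per tracked term; the ``baseline`` column holds ranks from the
    full profile, then one column per removed target, ordered by descending
    affinity (strong binders first, mirroring their expected impact).
    Terms absent from a re-scored result set get NaN.
    """
    if len(profile.targets) < 2:
        raise ValueError("leave-one-out needs at least 2 profiled targets")
    baseline = score_all(net, am, profile, collapse=collapse, min_size=min_size)
    matrix: dict[str, list[float]] = {
        "baseline": [_rank_of(baseline, t) for t in tracked_terms]
    }
    order = sorted(profile.targets, key=lambda t: (-t.a_t, t.protein_id))
    for target in order:
        reduced = profile.without(target.protein_id)
        results = score_all(net, am, reduced, collapse=collapse, min_size=min_size)
        matrix[target.protein_id] = [_rank_of(results, t) for t in tracked_terms]
    df = pd.DataFrame(matrix, index=pd.Index(tracked_terms, name="term"))
    logger.info(
        "[robustness] leave-one-out over %d targets, %d tracked terms",
        len(order), len(tracked_terms),
    )
    return df


def hub_weighting(
    net: Interactome,
    am: AnnotationMap,
    profile: TargetProfile,
    mode: str,
    collapse: bool = False,
    min_size: int = 1,
) -> list[ScoreResult]:
    """Re-score with target affinities scaled by log10 of node degree.

    ``mode='up'``: a_t ← a_t · log10(degree); emphasizes hubs. Degree-1
    targets (log10 = 0) get a_t = 0.
    ``mode='down'``: a_t ← a_t / log10(degree); de-emphasizes hubs.
    Degree-1 targets would divide by zero, so their a_t is left unchanged
    with a warning. Targets absent from the interactome keep their a_t
    unweighted, with a warning. T_drug is recomputed before scoring.
    """
    if mode not in ("up", "down"):
        raise ValueError(f"mode must be 'up' or 'down', got {mode!r}")
    new_a: dict[str, float] = {}
    for t in profile.targets:
        if t.protein_id not in net:
            logger.warning(
                "[robustness] target %s absent from interactome; affinity unweighted",
                t.protein_id,
            )
            continue
        w = np.log10(net.degree(t.protein_id))
        if mode == "up":
            new_a[t.protein_id] = t.a_t * w
        else:
            if w == 0:
                logger.warning(
                    "[robustness] target %s has degree 1; affinity left unchanged "
                    "in down mode", t.protein_id,
                )
                continue
            new_a[t.protein_id] = t.a_t / w
    reweighted = profile.reweighted(new_a)
    return score_all(net, am, reweighted, collapse=collapse, min_size=min_size)
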