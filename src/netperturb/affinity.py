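"""Per-target affinity scores from competition chemical proteomics.

In a competition pulldown the free (soluble) drug blocks its real targets'
binding pockets, so the amount of each specific target captured on the
immobilized drug — proxied by its peptide count — drops. The affinity score
combines that competition-driven depletion with a log-damped abundance term:

    a_t = (1 − p_comp / p_t) · log10(p_t)

where ``p_t`` is the peptide count without and ``p_comp`` with competition.
The first factor is the fraction competed away; the logarithm of ``p_t``
keeps highly abundant proteins from dominating while still separating
completely competed targets by amount. Sporadically ``p_comp > p_t`` (the
competed pulldown is less complex); this is read as no competition and the
affinity is set to 0.

When competition data are unavailable, externally measured potencies (e.g.
kinase IC50s) can be supplied instead, passed through a configurable
transform. The default transform is log10 of the nM value; because larger
IC50 means weaker inhibition this direction is debatable, so ``neglog10``
(−log10, emphasizing potent inhibitors) is offered as the alternative.

The logarithm base is 10 throughout. The base only rescales every a_t by a
constant, which cancels in the scoring ratio T_drug,net / T_drug, so
rankings within one profile do not depend on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import ProfileRow

logger = logging.getLogger(__name__)

__all__ = ["Target", "TargetProfile", "affinity_score", "external_weight", "build_profile"]

TRANSFORMS = ("log10", "neglog10", "identity")


@dataclass(frozen=True)
class Target:
    """One profiled drug target with its computed affinity score."""

    protein_id: str
    a_t: float
    p_t: int | None = None
    p_comp: int | None = None


@dataclass
class TargetProfile:
    """The full drug target profile with per-target affinities.

    ``t_drug`` is the overall affinity of all possible drug targets,
    Σ a_t over every profiled protein — including targets that never appear
    in the interactome, which therefore contribute to the scoring
    denominator but can never be captured by any sub-network.
    """

    targets: list[Target]
    mode: str  # "competition_counts" | "external_weights"
    t_drug: float = field(init=False)

    def __post_init__(self) -> None:
        if any(t.a_t < 0 for t in self.targets):
            raise ValueError("affinity scores must be non-negative")
        self.t_drug = sum(t.a_t for t in sorted(self.targets, key=lambda t: t.protein_id))

    @property
    def target_ids(self) -> set[str]:
        return {t.protein_id for t in self.targets}

    @property
    def affinities(self) -> dict[str, float]:
        return {t.protein_id: t.a_t for t in self.targets}

    def without(self, protein_id: str) -> "TargetProfile":
        """Profile with one target removed and t_drug recomputed."""
        kept = [t for t in self.targets if t.protein_id != protein_id]
        if len(kept) == len(self.targets):
            raise KeyError(f"{protein_id!r} is not in the profile")
        if not kept:
            raise ValueError("cannot remove the only target of a profile")
        return TargetProfile(kept, self.mode)

    def reweighted(self, new_affinities: dict[str, float]) -> "TargetProfile":
        """Profile with per-target affinities replaced; t_drug recomputed."""
        targets = [
            Target(t.protein_id, new_affinities.get(t.protein_id, t.a_t), t.p_t, t.p_comp)
            for t in self.targets
        ]
        return TargetProfile(targets, self.mode)


def affinity_score(p_t: int, p_comp: int) -> float:
    """Competition affinity a_t = (1 − p_comp/p_t) · log10(p_t).

    ``p_comp ≥ p_t`` (no competition observed) gives exactly 0. A protein
    cannot be profiled with zero peptides, so ``p_t < 1`` is an error.
    Note the log10 factor: a single-peptide protein (p_t = 1) scores 0
    even when fully competed.
    """
    if p_t < 1:
        raise ValueError("p_t must be a positive peptide count")
    if p_comp < 0:
        raise ValueError("p_comp must be non-negative")
    if p_comp >= p_t:
        return 0.0
    return (1.0 - p_comp / p_t) * math.log10(p_t)


def external_weight(raw: float, transform: str = "log10") -> float:
    """Transform an external potency into a non-negative weight.

    Negative transformed values (e.g. log10 of a sub-1 nM IC50) are clamped
    to 0 with a warning rather than allowed to subtract from T_drug.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if raw <= 0:
        raise ValueError("external potency must be positive")
    if transform == "log10":
        value = math.log10(raw)
    elif transform == "neglog10":
        value = -math.log10(raw)
    else:
        value = raw
    if value < 0:
        logger.warning(
            "[affinity] %s(%g) = %g is negative; clamped to 0", transform, raw, value
        )
        return 0.0
    return value


def build_profile(rows: Iterable[ProfileRow], transform: str = "log10") -> TargetProfile:
    """Compute a :class:`TargetProfile` from parsed profile rows.

    All rows must share one mode. In count mode a missing ``p_comp`` is
    treated as not competed (p_comp = p_t, hence a_t = 0) and logged.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("empty target profile")
    modes = {r.external_weight is not None for r in rows}
    if len(modes) > 1:
        raise ValueError("profile mixes count rows and weight rows")
    weight_mode = modes.pop()

    targets: list[Target] = []
    n_missing = 0
    for r in rows:
        if weight_mode:
            targets.append(Target(r.protein_id, external_weight(r.external_weight, transform)))
        else:
            p_comp = r.p_comp
            if p_comp is None:
                n_missing += 1
                p_comp = r.p_t
            targets.append(
                Target(r.protein_id, affinity_score(r.p_t, p_comp), p_t=r.p_t, p_comp=p_comp)
            )
    if n_missing:
        logger.info(
            "[affinity] %d target(s) without competition counts treated as not competed",
            n_missing,
        )
    profile = TargetProfile(targets, "external_weights" if weight_mode else "competition_counts")
    logger.info(
        "[affinity] %d targets, %d with a_t > 0, T_drug = %.4g",
        len(targets), sum(1 for t in targets if t.a_t > 0), profile.t_drug,
    )
    return profile
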