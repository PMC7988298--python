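"""Supply-to-demand adaptation (SDA) scores.

SDAw(c) = supply fraction of codon c / demand fraction of codon c, both
sides sum-to-one over the sense codons.  SDAw = 1 means decoding supply
exactly matches codon demand; codons above 2 are conventionally called
favored and codons below 0.5 disfavored.  The gene-level SDA is the
geometric mean of SDAw over the gene's codon occurrences, and ΔSDA is the
difference of gene SDA between two conditions (each condition summarized
by the arithmetic mean of its samples' SDAw per codon).

Note on the formula: the sum-to-one fraction-ratio definition used here is
a reconstruction that reproduces the documented balance point (SDAw = 1
when supply matches demand) and the favored/disfavored thresholds; see
docs/methods.md for the full contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .codons import CodonError
from .weights import CDSSet, CodonWeights, Normalization, rcu

logger = logging.getLogger(__name__)

__all__ = [
    "CodonClass",
    "GeneScore",
    "ScoreKind",
    "SDAProfile",
    "classify_codon",
    "delta_sda",
    "gene_sda",
    "mean_profile",
    "rcu_scores",
    "sda_weights",
]


class CodonClass(str, Enum):
    FAVORED = "FAVORED"
    BALANCED = "BALANCED"
    DISFAVORED = "DISFAVORED"


class ScoreKind(str, Enum):
    GENE_SDA = "GENE_SDA"
    DELTA_SDA = "DELTA_SDA"
    RCU = "RCU"


@dataclass
class SDAProfile:
    """Per-codon SDAw for one sample (or one condition summary)."""

    sample_id: str
    sdaw: dict[str, float]

    def __post_init__(self) -> None:
        if not self.sdaw:
            raise ValueError(f"{self.sample_id}: empty SDAw profile")
        bad = [c for c, v in self.sdaw.items() if not (math.isfinite(v) and v > 0)]
        if bad:
            raise ValueError(f"{self.sample_id}: non-positive SDAw for {sorted(bad)}")


@dataclass(frozen=True)
class GeneScore:
    """A per-gene scalar used as a ranking statistic."""

    gene_id: str
    score: float
    kind: ScoreKind

    def __post_init__(self) -> None:
        if self.kind is ScoreKind.GENE_SDA and not self.score > 0:
            raise ValueError(f"{self.gene_id}: gene SDA must be positive")
        if self.kind is ScoreKind.RCU and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"{self.gene_id}: RCU must lie in [0, 1]")


def sda_weights(
    supply: CodonWeights, demand: CodonWeights, *, sample_id: str | None = None
) -> SDAProfile:
    """Per-codon SDAw = supply fraction / demand fraction.

    Both inputs must be SUM1-normalized over the same codon universe.
    Codons with zero demand (possible in tiny CDS sets) have no defined
    SDAw and are dropped with a warning — never reported as infinite.
    Codons with zero supply (only possible when zero-imputation was
    disabled upstream) are dropped likewise.
    """
    if (
        supply.normalization is not Normalization.SUM1
        or demand.normalization is not Normalization.SUM1
    ):
        raise ValueError("sda_weights requires SUM1-normalized supply and demand")
    if set(supply.values) != set(demand.values):
        raise ValueError("supply and demand cover different codon universes")
    dropped = [c for c in supply.values if demand.values[c] == 0 or supply.values[c] == 0]
    if dropped:
        logger.warning(
            "%s: dropping %d codon(s) with zero supply or demand: %s",
            sample_id or "<sda>",
            len(dropped),
            sorted(dropped),
        )
    sdaw = {
        c: supply.values[c] / demand.values[c]
        for c in supply.values
        if c not in dropped
    }
    return SDAProfile(sample_id or "<sda>", sdaw)


def classify_codon(
    sdaw_value: float,
    *,
    favored_threshold: float = 2.0,
    disfavored_threshold: float = 0.5,
) -> CodonClass:
    """Classify a codon by its SDAw: > 2 favored, < 0.5 disfavored.

    Thresholds are strict inequalities, so the boundary values map to
    BALANCED.
    """
    if not (math.isfinite(sdaw_value) and sdaw_value > 0):
        raise CodonError(f"SDAw must be a positive finite number, got {sdaw_value}")
    if sdaw_value > favored_threshold:
        return CodonClass.FAVORED
    if sdaw_value < disfavored_threshold:
        return CodonClass.DISFAVORED
    return CodonClass.BALANCED


def gene_sda(cds: CDSSet, gene_id: str, profile: SDAProfile) -> GeneScore:
    """Gene-level SDA: geometric mean of SDAw over the gene's codons.

    Every codon occurrence counts once; stop codons never contribute.
    Computed in log space: exp(Σ n_c·log SDAw(c) / Σ n_c).  Codons the
    profile dropped (zero demand upstream) are skipped.
    """
    counts = cds.counts(gene_id)
    if not counts:
        raise ValueError(f"{gene_id}: no sense codons, gene SDA undefined")
    usable = {c: n for c, n in counts.items() if c in profile.sdaw}
    if not usable:
        raise ValueError(
            f"{gene_id}: none of the gene's codons has a defined SDAw in "
            f"profile {profile.sample_id}"
        )
    total = sum(usable.values())
    log_mean = sum(n * math.log(profile.sdaw[c]) for c, n in usable.items()) / total
    return GeneScore(gene_id, math.exp(log_mean), ScoreKind.GENE_SDA)


def mean_profile(
    profiles: Sequence[SDAProfile], sample_id: str = "mean"
) -> SDAProfile:
    """Arithmetic mean of SDAw per codon over samples of one condition.

    Codons are restricted to those defined in every sample.
    """
    if not profiles:
        raise ValueError("cannot average an empty list of SDA profiles")
    common = set(profiles[0].sdaw)
    for p in profiles[1:]:
        common &= set(p.sdaw)
    if not common:
        raise ValueError("no codon is defined in every profile")
    return SDAProfile(
        sample_id,
        {c: sum(p.sdaw[c] for p in profiles) / len(profiles) for c in common},
    )


def _as_profile(x: SDAProfile | Sequence[SDAProfile], label: str) -> SDAProfile:
    if isinstance(x, SDAProfile):
        return x
    return mean_profile(list(x), sample_id=label)


def delta_sda(
    profile_a: SDAProfile | Sequence[SDAProfile],
    profile_b: SDAProfile | Sequence[SDAProfile],
    cds: CDSSet,
    *,
    gene_ids: Iterable[str] | None = None,
) -> list[GeneScore]:
    """Per-gene ΔSDA = gene SDA under condition A − gene SDA under B.

    Cohort inputs (sequences of per-sample profiles) are first summarized
    by the per-codon arithmetic mean of SDAw.  Output is sorted by score
    descending with a stable gene-id tiebreak.
    """
    pa = _as_profile(profile_a, "condition_a")
    pb = _as_profile(profile_b, "condition_b")
    genes = list(gene_ids) if gene_ids is not None else cds.genes
    genes = [g for g in genes if g in cds]
    if not genes:
        raise ValueError("no shared genes to score")
    scores = [
        GeneScore(
            g,
            gene_sda(cds, g, pa).score - gene_sda(cds, g, pb).score,
            ScoreKind.DELTA_SDA,
        )
        for g in genes
    ]
    scores.sort(key=lambda s: (-s.score, s.gene_id))
    return scores


def rcu_scores(cds: CDSSet, codon: str) -> list[GeneScore]:
    """Relative codon usage of one codon across all genes, as GeneScores.

    Genes in which the codon's synonymous family is absent (RCU undefined)
    are omitted, not scored 0.
    """
    out = []
    for g in cds.genes:
        v = rcu(cds, g, codon)
        if v is not None:
            out.append(GeneScore(g, v, ScoreKind.RCU))
    return out
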