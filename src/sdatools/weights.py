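"""Per-codon tRNA supply and expression-weighted codon demand.

Supply is the tAI-style decoding capacity of a tRNA repertoire: for each
sense codon, the abundances of its decoder anticodons are summed after
discounting wobble pairs by ``1 - s``.  Demand is the transcriptome-wide
codon usage weighted by mRNA abundance.  Both sides are returned as
labeled relative frequencies (sum-to-one) over the 61 sense codons, ready
for the SDAw ratio in :mod:`sdatools.sda`.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .codons import (
    COMPLEMENT,
    SENSE_CODONS,
    STOP_CODONS,
    CodonError,
    PairingRule,
    amino_acid,
    synonymous_family,
    _check_triplet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CDSSet",
    "CodonWeights",
    "ExpressionProfile",
    "Normalization",
    "Side",
    "TRNAProfile",
    "codon_counts",
    "demand_weights",
    "rcu",
    "stop_codon_count",
    "supply_weights",
]


class Side(str, Enum):
    SUPPLY = "SUPPLY"
    DEMAND = "DEMAND"


class Normalization(str, Enum):
    RAW = "RAW"
    MAX1 = "MAX1"
    SUM1 = "SUM1"


@dataclass
class TRNAProfile:
    """Anticodon-level tRNA abundances for one sample.

    Units are arbitrary but must be consistent within the profile (read
    counts, gene copy numbers, normalized abundances ...); every
    downstream use is scale-invariant.
    """

    sample_id: str
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        for anticodon in self.abundance:
            _check_triplet(anticodon, "anticodon")
        vals = list(self.abundance.values())
        if any(not math.isfinite(v) or v < 0 for v in vals):
            raise ValueError(f"{self.sample_id}: tRNA abundances must be finite and >= 0")
        if not vals or not any(v > 0 for v in vals):
            raise ValueError(f"{self.sample_id}: tRNA profile is empty or all-zero")


@dataclass
class ExpressionProfile:
    """Per-gene mRNA abundance (TPM-like units) for one sample."""

    sample_id: str
    tpm: dict[str, float]

    def __post_init__(self) -> None:
        if any(not g for g in self.tpm):
            raise ValueError(f"{self.sample_id}: empty gene id in expression profile")
        if any(not math.isfinite(v) or v < 0 for v in self.tpm.values()):
            raise ValueError(f"{self.sample_id}: expression values must be finite and >= 0")


class CDSSet:
    """A set of coding sequences, gene id → in-frame DNA string.

    Sequences are read from position 0 in non-overlapping triplets.  A
    trailing stop codon is expected and excluded from codon counts.
    Internal stop codons raise in ``strict`` mode and warn in ``lenient``
    mode (default), since real CDS annotations are imperfect.
    """

    def __init__(self, sequences: Mapping[str, str], mode: str = "lenient") -> None:
        if mode not in ("lenient", "strict"):
            raise ValueError(f"unknown CDS validation mode {mode!r}")
        self.mode = mode
        self._seqs: dict[str, str] = {}
        n_internal_stops = 0
        for gene_id, seq in sequences.items():
            if not gene_id:
                raise ValueError("empty gene id in CDS set")
            seq = seq.upper()
            if len(seq) < 3 or len(seq) % 3 != 0:
                raise ValueError(
                    f"CDS {gene_id}: length {len(seq)} is not a positive multiple of 3"
                )
            if any(b not in COMPLEMENT for b in seq):
                raise ValueError(f"CDS {gene_id}: non-ACGT characters present")
            triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            internal = sum(t in STOP_CODONS for t in triplets[:-1])
            if internal:
                n_internal_stops += internal
                if mode == "strict":
                    raise ValueError(f"CDS {gene_id}: {internal} internal stop codon(s)")
            self._seqs[gene_id] = seq
        if n_internal_stops:
            warnings.warn(
                f"CDS set contains {n_internal_stops} internal stop codon(s) "
                "(lenient mode: kept, excluded from sense counts)",
                stacklevel=2,
            )
        self._counts: dict[str, Counter[str]] = {}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __getitem__(self, gene_id: str) -> str:
        return self._seqs[gene_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CDSSet) and self._seqs == other._seqs

    @property
    def genes(self) -> list[str]:
        return list(self._seqs)

    def items(self):
        return self._seqs.items()

    def counts(self, gene_id: str) -> Counter[str]:
        """Cached sense-codon counts for one gene (stops excluded)."""
        if gene_id not in self._counts:
            seq = self._seqs[gene_id]  # KeyError for absent gene, as specified
            c = Counter(seq[i : i + 3] for i in range(0, len(seq), 3))
            for stop in STOP_CODONS:
                del c[stop]
            self._counts[gene_id] = c
        return self._counts[gene_id]


@dataclass
class CodonWeights:
    """A labeled codon → weight map for one side of the SDA ratio."""

    side: Side
    values: dict[str, float]
    normalization: Normalization = Normalization.RAW

    def __post_init__(self) -> None:
        bad = set(self.values) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codon keys in weights: {sorted(bad)}")
        if any(not math.isfinite(v) or v < 0 for v in self.values.values()):
            raise ValueError("codon weights must be finite and >= 0")
        if self.normalization is Normalization.SUM1:
            total = sum(self.values.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"SUM1 weights sum to {total}, not 1")
        elif self.normalization is Normalization.MAX1:
            if abs(max(self.values.values()) - 1.0) > 1e-9:
                raise ValueError("MAX1 weights must have maximum 1")

    def normalized(self, normalization: Normalization = Normalization.SUM1) -> "CodonWeights":
        if normalization is Normalization.RAW:
            return CodonWeights(self.side, dict(self.values), Normalization.RAW)
        if normalization is Normalization.SUM1:
            total = sum(self.values.values())
            if total <= 0:
                raise ValueError("cannot SUM1-normalize all-zero weights")
            vals = {c: v / total for c, v in self.values.items()}
        else:
            top = max(self.values.values())
            if top <= 0:
                raise ValueError("cannot MAX1-normalize all-zero weights")
            vals = {c: v / top for c, v in self.values.items()}
        return CodonWeights(self.side, vals, normalization)


def supply_weights(
    trna: TRNAProfile,
    rules: Iterable[PairingRule],
    *,
    impute_zeros: bool = True,
    on_unknown_anticodon: str = "error",
    normalization: Normalization = Normalization.SUM1,
) -> CodonWeights:
    """tAI-style per-codon decoding supply from a tRNA repertoire.

    Raw weight W(c) = Σ over rules (c, a) of (1 - s) · abundance(a).
    Anticodons absent from the profile contribute 0 (logged); anticodons
    in the profile that decode nothing under ``rules`` raise by default.
    Codons with W = 0 (no decoder observed) are imputed with the geometric
    mean of the non-zero weights before normalization — the reference tAI
    convention, without which downstream geometric means collapse to 0 —
    unless ``impute_zeros=False``.
    """
    rules = list(rules)
    decoder_anticodons = {r.anticodon for r in rules}
    unknown = sorted(set(trna.abundance) - decoder_anticodons)
    if unknown:
        if on_unknown_anticodon == "error":
            raise ValueError(
                f"{trna.sample_id}: anticodons with no pairing rule: {unknown}"
            )
        logger.info("%s: ignoring %d non-decoding anticodons", trna.sample_id, len(unknown))
    missing = decoder_anticodons - set(trna.abundance)
    if missing:
        logger.info(
            "%s: %d decoder anticodons absent from profile, treated as 0",
            trna.sample_id,
            len(missing),
        )

    raw = {c: 0.0 for c in SENSE_CODONS}
    for r in rules:
        raw[r.codon] += r.efficiency * trna.abundance.get(r.anticodon, 0.0)
    if all(v == 0 for v in raw.values()):
        raise ValueError(f"{trna.sample_id}: supply is zero for every codon")
    if impute_zeros:
        nonzero = [v for v in raw.values() if v > 0]
        gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
        n_imputed = 0
        for c, v in raw.items():
            if v == 0:
                raw[c] = gm
                n_imputed += 1
        if n_imputed:
            logger.info("%s: imputed %d zero-supply codons", trna.sample_id, n_imputed)
    return CodonWeights(Side.SUPPLY, raw).normalized(normalization)


def codon_counts(cds: CDSSet, gene_id: str) -> dict[str, int]:
    """Sense-codon counts of one gene (non-overlapping, frame 0).

    Stop codons are excluded; use :func:`stop_codon_count` for them.
    """
    return dict(cds.counts(gene_id))


def stop_codon_count(cds: CDSSet, gene_id: str) -> int:
    seq = cds[gene_id]
    return sum(
        seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq), 3)
    )


def demand_weights(expr: ExpressionProfile, cds: CDSSet) -> CodonWeights:
    """Expression-weighted codon usage: U(c) = Σ_g tpm(g) · count_c(g).

    Computed over the genes shared between the expression profile and the
    CDS set, then sum-to-one normalized over the 61 sense codons.
    """
    shared = [g for g in cds.genes if g in expr.tpm]
    if not shared:
        raise ValueError(
            f"{expr.sample_id}: no gene ids shared between expression and CDS set"
        )
    n_unmatched = (len(expr.tpm) - len(shared)) + (len(cds) - len(shared))
    if n_unmatched:
        logger.warning(
            "%s: %d gene ids present on only one side of the expression/CDS join",
            expr.sample_id,
            n_unmatched,
        )
    raw = {c: 0.0 for c in SENSE_CODONS}
    for g in shared:
        t = expr.tpm[g]
        if t == 0:
            continue
        for c, n in cds.counts(g).items():
            raw[c] += t * n
    return CodonWeights(Side.DEMAND, raw).normalized(Normalization.SUM1)


def rcu(cds: CDSSet, gene_id: str, codon: str) -> float | None:
    """Relative codon usage of ``codon`` within one gene.

    Count of the codon divided by the summed counts of its synonymous
    family in that gene.  Returns ``None`` (undefined, not 0) when the
    gene uses no codon of the family at all.
    """
    _check_triplet(codon)
    if codon in STOP_CODONS:
        raise CodonError(f"RCU is undefined for stop codon {codon}")
    counts = cds.counts(gene_id)
    family_total = sum(counts.get(c, 0) for c in synonymous_family(codon))
    if family_total == 0:
        return None
    return counts.get(codon, 0) / family_total
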