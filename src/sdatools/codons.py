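"""Genetic-code primitives and codon–anticodon wobble pairing rules.

Every public collection in this module is keyed by codon or anticodon
*string* (DNA alphabet, 5'→3').  Positional 64-vectors — the classic source
of off-by-one bugs in tAI-style pipelines, where a misplaced stop codon
silently scrambles the pairing rules for every codon after it — are never
accepted or produced here; they exist only inside explicit I/O adapters
(see :mod:`sdatools.io`) that carry their own codon-order manifest.

The wobble model follows the tAI convention: each sense codon is decoded by
its Watson–Crick anticodon at full efficiency plus at most one (two, with
the prokaryotic C34:A3 rule enabled) wobble anticodon whose efficiency is
discounted by a selective-constraint penalty ``s`` in [0, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "ALL_CODONS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "AMINO_ACID_FAMILIES",
    "CodonError",
    "PairClass",
    "PairingRule",
    "SParams",
    "amino_acid",
    "anticodon_to_codon",
    "build_pairing_rules",
    "codon_to_anticodon",
    "decoders_of",
    "is_sense",
    "is_stop",
    "reverse_complement",
    "rules_from_tsv",
    "rules_to_tsv",
    "synonymous_family",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: All 64 codons in lexicographic order (used only for iteration, never as
#: an implicit index).
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid (one-letter) → codons of its synonymous family, lexicographic.
AMINO_ACID_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = _STANDARD_TABLE.forward_table[_codon]
    AMINO_ACID_FAMILIES.setdefault(_aa, ())
    AMINO_ACID_FAMILIES[_aa] += (_codon,)


class CodonError(ValueError):
    """Raised for malformed codon/anticodon strings or stop-codon misuse."""


def _check_triplet(seq: str, what: str = "codon") -> str:
    if not isinstance(seq, str):
        raise CodonError(f"{what} must be a string, got {type(seq).__name__}")
    if len(seq) != 3 or any(b not in COMPLEMENT for b in seq):
        raise CodonError(f"invalid {what} {seq!r}: need 3 uppercase DNA bases")
    return seq


def is_stop(codon: str) -> bool:
    return _check_triplet(codon) in STOP_CODONS


def is_sense(codon: str) -> bool:
    return not is_stop(codon)


def amino_acid(codon: str) -> str:
    """One-letter amino acid of a sense codon (standard genetic code)."""
    _check_triplet(codon)
    if codon in STOP_CODONS:
        raise CodonError(f"{codon} is a stop codon and encodes no amino acid")
    return _STANDARD_TABLE.forward_table[codon]


def synonymous_family(codon: str) -> tuple[str, ...]:
    """All codons coding the same amino acid as ``codon`` (incl. itself)."""
    return AMINO_ACID_FAMILIES[amino_acid(codon)]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def codon_to_anticodon(codon: str) -> str:
    """Anticodon (5'→3', DNA) that Watson–Crick pairs with ``codon``.

    Bijective over the 64-codon set; the inverse is
    :func:`anticodon_to_codon`.
    """
    return reverse_complement(_check_triplet(codon))


def anticodon_to_codon(anticodon: str) -> str:
    return reverse_complement(_check_triplet(anticodon, "anticodon"))


class PairClass(str, Enum):
    """Admissible codon–anticodon interaction classes.

    The name encodes the anticodon position-34 nucleoside and the codon
    third base it reads, e.g. ``GU_34`` is G34 pairing codon-3 U; ``IC_34``
    and ``IA_34`` are inosine-34 (written A in the gene sequence) reading C
    and A; ``CA_34`` (lysidine-modified C34 reading A) occurs in
    prokaryotes only.
    """

    WATSON_CRICK = "WATSON_CRICK"
    GU_34 = "GU_34"
    IC_34 = "IC_34"
    IA_34 = "IA_34"
    UG_34 = "UG_34"
    CA_34 = "CA_34"


@dataclass(frozen=True)
class SParams:
    """Selective-constraint penalties per wobble class, each in [0, 1].

    Defaults are the standard tAI values (dos Reis parameterization); they
    are configuration, not hard-coded truth, and any may be overridden.
    ``strict_families`` suppresses U34:G3 wobble when the donor anticodon
    belongs to a different amino acid's tRNA (keeps ATG and TGG on their
    Watson–Crick decoder only, matching reference tAI behavior).
    """

    gu_34: float = 0.41
    ic_34: float = 0.28
    ia_34: float = 0.9999
    ug_34: float = 0.68
    ca_34: float = 0.89
    include_prokaryotic_CA: bool = False
    strict_families: bool = True

    def __post_init__(self) -> None:
        for name in ("gu_34", "ic_34", "ia_34", "ug_34", "ca_34"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"penalty {name}={v} outside [0, 1]")

    def penalty(self, pair_class: PairClass) -> float:
        if pair_class is PairClass.WATSON_CRICK:
            return 0.0
        return {
            PairClass.GU_34: self.gu_34,
            PairClass.IC_34: self.ic_34,
            PairClass.IA_34: self.ia_34,
            PairClass.UG_34: self.ug_34,
            PairClass.CA_34: self.ca_34,
        }[pair_class]


@dataclass(frozen=True, order=True)
class PairingRule:
    """One admissible codon–anticodon interaction.

    ``s`` is the selective-constraint penalty (0 for Watson–Crick pairs);
    decoding efficiency is ``1 - s``.
    """

    codon: str
    anticodon: str
    pair_class: PairClass = field(compare=False)
    s: float = field(compare=False)

    def __post_init__(self) -> None:
        _check_triplet(self.codon)
        _check_triplet(self.anticodon, "anticodon")
        if self.codon in STOP_CODONS:
            raise CodonError(f"no pairing rule may involve stop codon {self.codon}")
        # anticodon positions 35, 36 must WC-pair codon positions 2, 1
        if (
            self.anticodon[1] != COMPLEMENT[self.codon[1]]
            or self.anticodon[2] != COMPLEMENT[self.codon[0]]
        ):
            raise CodonError(
                f"anticodon {self.anticodon} cannot pair codon {self.codon}: "
                "positions 35/36 are not complementary"
            )
        wc = self.anticodon[0] == COMPLEMENT[self.codon[2]]
        if wc != (self.pair_class is PairClass.WATSON_CRICK):
            raise CodonError(
                f"pair class {self.pair_class.value} inconsistent with "
                f"{self.codon}/{self.anticodon} at the wobble position"
            )
        if self.pair_class is PairClass.WATSON_CRICK:
            if self.s != 0.0:
                raise CodonError("Watson–Crick pairs have s = 0 by definition")
        elif not (0.0 < self.s <= 1.0):
            raise CodonError(f"wobble penalty s={self.s} must lie in (0, 1]")

    @property
    def efficiency(self) -> float:
        return 1.0 - self.s


# wobble anticodon position-34 base and class, by codon third base
_WOBBLE_BY_THIRD_BASE = {
    "T": ("G", PairClass.GU_34),
    "C": ("A", PairClass.IC_34),
    "A": ("A", PairClass.IA_34),
    "G": ("T", PairClass.UG_34),
}


def build_pairing_rules(s_params: SParams | None = None) -> frozenset[PairingRule]:
    """Construct the full pairing-rule table for the 61 sense codons.

    Each sense codon gets exactly one Watson–Crick rule plus the wobble
    rule(s) dictated by its third base.  The result is an unordered set
    keyed by (codon, anticodon); there is no positional encoding anywhere.
    """
    s_params = s_params or SParams()
    rules: set[PairingRule] = set()
    for codon in SENSE_CODONS:
        stem = COMPLEMENT[codon[1]] + COMPLEMENT[codon[0]]  # anticodon pos 35,36
        rules.add(
            PairingRule(codon, reverse_complement(codon), PairClass.WATSON_CRICK, 0.0)
        )
        base34, pair_class = _WOBBLE_BY_THIRD_BASE[codon[2]]
        admit = True
        if pair_class is PairClass.UG_34 and s_params.strict_families:
            # the U34 donor anticodon belongs to the tRNA whose WC codon is
            # NNA; crossing into another amino acid's family is disallowed
            partner = codon[:2] + "A"
            admit = partner not in STOP_CODONS and amino_acid(partner) == amino_acid(
                codon
            )
        if admit:
            rules.add(
                PairingRule(codon, base34 + stem, pair_class, s_params.penalty(pair_class))
            )
        if codon[2] == "A" and s_params.include_prokaryotic_CA:
            rules.add(PairingRule(codon, "C" + stem, PairClass.CA_34, s_params.ca_34))
    return frozenset(rules)


def decoders_of(
    codon: str, rules: Iterable[PairingRule]
) -> list[tuple[str, float]]:
    """All (anticodon, efficiency) pairs decoding a sense codon.

    Watson–Crick first, then wobble rules ordered by pair-class name, so
    the output order is deterministic.
    """
    _check_triplet(codon)
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon} has no decoders")
    matching = [r for r in rules if r.codon == codon]
    matching.sort(key=lambda r: (r.pair_class is not PairClass.WATSON_CRICK, r.pair_class.value))
    return [(r.anticodon, r.efficiency) for r in matching]


def rules_to_tsv(rules: Iterable[PairingRule], path: str | Path) -> None:
    """Write a rule table as TSV (codon, anticodon, pair_class, s)."""
    lines = ["codon\tanticodon\tpair_class\ts"]
    for r in sorted(rules):
        lines.append(f"{r.codon}\t{r.anticodon}\t{r.pair_class.value}\t{r.s:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def rules_from_tsv(path: str | Path) -> frozenset[PairingRule]:
    """Read a rule table written by :func:`rules_to_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["codon", "anticodon", "pair_class", "s"]:
        raise ValueError(f"{path}: missing or malformed rule-table header")
    rules = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        codon, anticodon, pair_class, s = parts
        rules.add(PairingRule(codon, anticodon, PairClass(pair_class), float(s)))
    return frozenset(rules)


def codon_order_checksum(codons: Iterable[str]) -> str:
    """SHA-256 checksum of an explicit codon-order manifest.

    Positional 64-vector interchange formats are accepted only together
    with such a manifest, and the checksum is logged so that any silent
    reordering of the list is detectable.
    """
    return hashlib.sha256("\n".join(codons).encode()).hexdigest()
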