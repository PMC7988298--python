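"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own rule-construction and
vectorized code paths: the pairing oracle enumerates all 64 × 64
codon/anticodon combinations against a plain restatement of the wobble
rules, the supply oracle loops pair-by-pair, and the enrichment oracle
walks the ranking one gene at a time.
"""

from Bio.Seq import Seq

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRIPLETS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_pairing_rules(sp):
    """Enumerate admissible (codon, anticodon, class, s) over all 64 × 64."""
    out = set()
    for codon in _TRIPLETS:
        if codon in _STOPS:
            continue
        for anticodon in _TRIPLETS:
            # anticodon 35/36 must Watson-Crick pair codon positions 2/1
            if anticodon[1] != _COMP[codon[1]] or anticodon[2] != _COMP[codon[0]]:
                continue
            third, a34 = codon[2], anticodon[0]
            if a34 == _COMP[third]:
                out.add((codon, anticodon, "WATSON_CRICK", 0.0))
            elif third == "T" and a34 == "G":
                out.add((codon, anticodon, "GU_34", sp.gu_34))
            elif third == "C" and a34 == "A":
                out.add((codon, anticodon, "IC_34", sp.ic_34))
            elif third == "A" and a34 == "A":
                out.add((codon, anticodon, "IA_34", sp.ia_34))
            elif third == "A" and a34 == "C" and sp.include_prokaryotic_CA:
                out.add((codon, anticodon, "CA_34", sp.ca_34))
            elif third == "G" and a34 == "T":
                partner = codon[:2] + "A"
                if sp.strict_families and (
                    partner in _STOPS or _aa(partner) != _aa(codon)
                ):
                    continue
                out.add((codon, anticodon, "UG_34", sp.ug_34))
    return out


def oracle_supply(abundance, sp):
    """Raw (unnormalized, unimputed) supply weights by pairwise looping."""
    rules = oracle_pairing_rules(sp)
    raw = {c: 0.0 for c in _TRIPLETS if c not in _STOPS}
    for codon, anticodon, _cls, s in rules:
        raw[codon] += (1.0 - s) * abundance.get(anticodon, 0.0)
    return raw


def oracle_enrichment_score(ranked_items, gene_set, weight_exponent=1.0):
    """Weighted KS enrichment score by a one-gene-at-a-time walk.

    ``ranked_items`` is a list of (gene_id, score) already sorted by
    score descending.
    """
    hits = [g in gene_set for g, _ in ranked_items]
    n_miss = sum(1 for h in hits if not h)
    denom = sum(abs(v) ** weight_exponent for (g, v), h in zip(ranked_items, hits) if h)
    if denom == 0:
        denom = sum(hits)
        weights = [1.0 if h else 0.0 for h in hits]
    else:
        weights = [
            abs(v) ** weight_exponent if h else 0.0
            for (g, v), h in zip(ranked_items, hits)
        ]
    best, run = 0.0, 0.0
    for w, h in zip(weights, hits):
        run += w / denom if h else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best
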