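"""Synthetic cohorts with known planted structure.

Generates coding sequences, per-sample tRNA repertoires, and per-sample
expression tables for two labeled conditions, with optional planted
per-codon supply/demand imbalances and an optional continuous
"proliferation" factor coupled to a marker gene.  Every pipeline stage
can therefore be tested against ground truth without any downloads.

All randomness flows through numpy ``Generator`` streams derived from the
single configured seed, so a fixed seed reproduces byte-identical outputs
across platforms.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codons import SENSE_CODONS, STOP_CODONS, AMINO_ACID_FAMILIES, PairingRule, build_pairing_rules
from .sda import SDAProfile, sda_weights
from .weights import (
    CDSSet,
    ExpressionProfile,
    TRNAProfile,
    Side,
    demand_weights,
    supply_weights,
)
from .cohort import SDAMatrix

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "SyntheticCohort",
    "cohort_sda_matrix",
    "marker_expression",
    "planted_variance_share",
    "generate_cds",
    "generate_cohort",
]

_FAMILIES = sorted(AMINO_ACID_FAMILIES.items())  # deterministic order
_STOPS = sorted(STOP_CODONS)


@dataclass(frozen=True)
class PlantedEffect:
    """A planted per-codon imbalance between the two conditions.

    SUPPLY: condition B overexpresses the cognate isoacceptor — the
    abundance of the anticodon that Watson–Crick pairs ``codon`` is
    multiplied by ``fold_change`` (the tRNA-overexpression mechanism;
    wobble neighbors are perturbed only through the pairing rules, as in
    real repertoires).  DEMAND: condition B's gene expression is tilted
    toward genes rich in ``codon`` (see generate_cohort).
    """

    codon: str
    fold_change: float
    side: Side

    def __post_init__(self) -> None:
        if self.codon not in SENSE_CODONS:
            raise ValueError(f"planted codon {self.codon!r} is not a sense codon")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a modest two-condition bulk cohort: a few hundred
    genes of realistic CDS length, moderately biased codon usage
    (family-wise Dirichlet concentration 5), log-normal expression, and
    ~28% multiplicative noise (log-sd 0.25) on tRNA and mRNA abundances.
    """

    seed: int = 0
    n_genes: int = 200
    mean_cds_codons: int = 300
    codon_usage_concentration: float = 5.0
    expression_log_mean: float = 3.0
    expression_log_sd: float = 1.0
    n_samples_per_condition: int = 10
    planted_effects: tuple[PlantedEffect, ...] = ()
    marker_effect: float = 0.0
    # latent one-factor axis (proliferation-like): per-sample N(0,1) factor
    # scales the decoder anticodons of factor_codons by 2**(strength·f)
    factor_codons: tuple[str, ...] = ()
    factor_strength: float = 0.0
    noise_sd: float = 0.25
    trna_log_sd: float = 0.5
    marker_gene: str = "MKI67"
    condition_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.condition_labels[0] == self.condition_labels[1]:
            raise ValueError("condition labels must differ")
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        object.__setattr__(self, "factor_codons", tuple(self.factor_codons))
        for c in self.factor_codons:
            if c not in SENSE_CODONS:
                raise ValueError(f"factor codon {c!r} is not a sense codon")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for e in d["planted_effects"]:
            e["side"] = e["side"].value if isinstance(e["side"], Side) else e["side"]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["planted_effects"] = tuple(
            PlantedEffect(e["codon"], e["fold_change"], Side(e["side"]))
            for e in d.pop("planted_effects", [])
        )
        d["factor_codons"] = tuple(d.get("factor_codons", ()))
        d["condition_labels"] = tuple(d["condition_labels"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated two-condition cohort plus the truth that produced it.

    ``factor_values`` records the per-sample draw of the latent
    proliferation-like factor (0.0 when the factor is disabled), so
    planted structure can be quantified exactly.
    """

    cds: CDSSet
    expression: list[ExpressionProfile]
    trna: list[TRNAProfile]
    conditions: dict[str, str]
    truth: SimConfig
    factor_values: dict[str, float] = field(default_factory=dict)


def _gene_ids(config: SimConfig) -> list[str]:
    ids = [config.marker_gene] if config.marker_gene else []
    i = 1
    while len(ids) < config.n_genes:
        ids.append(f"gene_{i:04d}")
        i += 1
    return ids


def generate_cds(config: SimConfig) -> CDSSet:
    """Generate a CDS set under family-wise Dirichlet-multinomial usage.

    Each gene starts with ATG, ends with one stop, contains no internal
    stop, and draws its synonymous-codon choices from per-gene, per-family
    Dirichlet(concentration) frequencies.  Gene lengths (in codons,
    including start and stop) are Poisson around ``mean_cds_codons`` with
    a floor of 3.
    """
    rng = np.random.default_rng([0, config.seed])
    conc = config.codon_usage_concentration
    seqs: dict[str, str] = {}
    for gene_id in _gene_ids(config):
        total = max(3, int(rng.poisson(config.mean_cds_codons)))
        n_internal = total - 2
        aa_idx = rng.integers(0, len(_FAMILIES), size=n_internal)
        codons = np.empty(n_internal, dtype=object)
        for k, (_aa, fam) in enumerate(_FAMILIES):
            pos = np.flatnonzero(aa_idx == k)
            if pos.size == 0:
                continue
            if len(fam) == 1:
                codons[pos] = fam[0]
            else:
                theta = rng.dirichlet(np.full(len(fam), conc))
                picks = rng.choice(len(fam), size=pos.size, p=theta)
                codons[pos] = np.array(fam, dtype=object)[picks]
        stop = _STOPS[rng.integers(len(_STOPS))]
        seqs[gene_id] = "ATG" + "".join(codons) + stop
    return CDSSet(seqs, mode="strict")


def generate_cohort(
    config: SimConfig, rules: frozenset[PairingRule] | None = None
) -> SyntheticCohort:
    """Generate the full two-condition cohort described by ``config``.

    Per sample, anticodon abundances and gene expression are the shared
    baselines perturbed by log-normal noise; condition B additionally
    carries the planted fold changes (on the cognate anticodon for SUPPLY
    effects; as an expression tilt toward codon-rich genes for DEMAND
    effects, tpm_g ← tpm_g · fold^(f_g/mean f) with f_g the gene's
    frequency of the planted codon).  The latent factor, when enabled,
    moves the factor codons' cognate anticodons and the marker gene
    together.
    """
    rules = rules if rules is not None else build_pairing_rules()
    decoders: dict[str, list[str]] = {}
    for r in rules:
        decoders.setdefault(r.codon, []).append(r.anticodon)
    anticodons = sorted({r.anticodon for r in rules})
    # planted/factor effects are carried by the cognate (Watson-Crick)
    # isoacceptor; it must exist in the repertoire the rules define
    from .codons import codon_to_anticodon

    def _cognate(codon: str, what: str) -> str:
        if not decoders.get(codon):
            raise ValueError(f"{what} codon {codon} has no decoder anticodon")
        ac = codon_to_anticodon(codon)
        if ac not in {a for a in decoders[codon]}:
            raise ValueError(f"{what} codon {codon}: cognate anticodon {ac} not in rules")
        return ac

    planted_carrier = {
        e: _cognate(e.codon, "planted")
        for e in config.planted_effects
        if e.side is Side.SUPPLY
    }
    factor_carrier = {c: _cognate(c, "factor") for c in config.factor_codons}
    ac_index = {a: i for i, a in enumerate(anticodons)}
    cds = generate_cds(config)
    genes = cds.genes
    g_index = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng([1, config.seed])
    base_log_ab = rng.normal(math.log(100.0), config.trna_log_sd, size=len(anticodons))
    base_log_tpm = rng.normal(
        config.expression_log_mean, config.expression_log_sd, size=len(genes)
    )

    # per-gene exponents for DEMAND-side planting
    demand_expo: dict[PlantedEffect, np.ndarray] = {}
    for e in config.planted_effects:
        if e.side is not Side.DEMAND:
            continue
        freq = np.array(
            [cds.counts(g).get(e.codon, 0) / (len(cds[g]) // 3) for g in genes]
        )
        mean_f = freq.mean()
        demand_expo[e] = freq / mean_f if mean_f > 0 else np.zeros_like(freq)

    srng = np.random.default_rng([2, config.seed])
    label_a, label_b = config.condition_labels
    expression: list[ExpressionProfile] = []
    trna: list[TRNAProfile] = []
    conditions: dict[str, str] = {}
    factor_values: dict[str, float] = {}
    for label in (label_a, label_b):
        for i in range(config.n_samples_per_condition):
            sample_id = f"{label}_{i + 1:02d}"
            factor = float(srng.normal())
            log_ab = base_log_ab + srng.normal(0.0, config.noise_sd, len(anticodons))
            log_tpm = base_log_tpm + srng.normal(0.0, config.noise_sd, len(genes))
            if label == label_b:
                for e in config.planted_effects:
                    if e.side is Side.SUPPLY:
                        log_ab[ac_index[planted_carrier[e]]] += math.log(e.fold_change)
                    else:
                        log_tpm += math.log(e.fold_change) * demand_expo[e]
            if config.factor_strength:
                for c in config.factor_codons:
                    log_ab[ac_index[factor_carrier[c]]] += (
                        math.log(2.0) * config.factor_strength * factor
                    )
            if config.marker_effect and config.marker_gene:
                log_tpm[g_index[config.marker_gene]] += config.marker_effect * factor
            trna.append(
                TRNAProfile(sample_id, dict(zip(anticodons, np.exp(log_ab).tolist())))
            )
            expression.append(
                ExpressionProfile(sample_id, dict(zip(genes, np.exp(log_tpm).tolist())))
            )
            conditions[sample_id] = label
            factor_values[sample_id] = factor
    return SyntheticCohort(cds, expression, trna, conditions, config, factor_values)


def cohort_sda_matrix(
    cohort: SyntheticCohort,
    rules: frozenset[PairingRule] | None = None,
) -> SDAMatrix:
    """Run the supply/demand/SDAw pipeline over every sample of a cohort."""
    rules = rules if rules is not None else build_pairing_rules()
    profiles: list[SDAProfile] = []
    for tp, ep in zip(cohort.trna, cohort.expression):
        supply = supply_weights(tp, rules)
        demand = demand_weights(ep, cohort.cds)
        profiles.append(sda_weights(supply, demand, sample_id=tp.sample_id))
    return SDAMatrix.from_profiles(profiles, cohort.conditions)


def planted_variance_share(
    cohort: SyntheticCohort,
    matrix: SDAMatrix | None = None,
    rules: frozenset[PairingRule] | None = None,
) -> float:
    """Fraction of the cohort's log2-SDAw variance carried by its factor.

    Regresses each codon's per-codon-centered log2 SDAw on the recorded
    latent factor values and returns the fitted sum of squares over the
    total.  This is the variance of the best rank-1 approximation whose
    sample-space axis is the true factor, so the first principal
    component of the same matrix always explains at least this share.
    """
    if matrix is None:
        matrix = cohort_sda_matrix(cohort, rules)
    f = np.array([cohort.factor_values[s] for s in matrix.samples])
    X = np.log2(matrix.values.to_numpy())
    X = X - X.mean(axis=0)
    f = f - f.mean()
    ss_f = float(f @ f)
    if ss_f == 0:
        return 0.0
    beta = X.T @ f / ss_f
    ss_fit = float(beta @ beta) * ss_f
    ss_total = float((X**2).sum())
    return ss_fit / ss_total if ss_total > 0 else 0.0


def marker_expression(cohort: SyntheticCohort) -> dict[str, float]:
    """Per-sample expression of the cohort's marker gene."""
    gene = cohort.truth.marker_gene
    return {e.sample_id: e.tpm[gene] for e in cohort.expression}
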