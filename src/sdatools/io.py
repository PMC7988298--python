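"""Readers and writers for the pipeline's plain-text formats.

FASTA for coding sequences, TSV for tRNA abundances / expression / SDAw
matrices / result tables, GMT for gene sets, JSON for simulation truth.
Positional 64-vector interchange (the input convention of classic tAI
tooling) is supported only through an explicit codon-order manifest whose
checksum is logged, so a silently reordered list can never scramble the
codon assignment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import ALL_CODONS, codon_order_checksum, codon_to_anticodon
from .cohort import DifferentialResult, EnrichmentResult, SDAMatrix
from .sda import GeneScore, ScoreKind, SDAProfile
from .simulate import SimConfig, SyntheticCohort
from .weights import CDSSet, ExpressionProfile, TRNAProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "read_fasta_cds",
    "read_gene_scores",
    "read_gmt",
    "read_positional_trna",
    "read_sdaw_matrix",
    "read_trna_table",
    "write_cohort",
    "write_differential_results",
    "write_enrichment_results",
    "write_expression_table",
    "write_fasta_cds",
    "write_gene_scores",
    "write_gmt",
    "write_sdaw_matrix",
    "write_trna_table",
]


# ---------------------------------------------------------------- FASTA


def read_fasta_cds(path: str | Path, mode: str = "lenient") -> CDSSet:
    """Read a CDS FASTA; record id up to first whitespace is the gene id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return CDSSet(seqs, mode=mode)


def write_fasta_cds(cds: CDSSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in cds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------ TSV


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _by_sample(df: pd.DataFrame, path, key: str, value: str, default_id: str):
    """Split a long-format table on its optional ``sample`` column."""
    if "sample" not in df.columns:
        df = df.assign(sample=default_id)
    out = {}
    for sample_id, sub in df.groupby("sample", sort=True):
        dup = sub[key][sub[key].duplicated()]
        if not dup.empty:
            rows = [int(i) + 2 for i in dup.index[:5]]
            raise ValueError(
                f"{path}: duplicate {key} {sorted(set(dup))} for sample "
                f"{sample_id} (lines {rows})"
            )
        out[str(sample_id)] = dict(zip(sub[key].astype(str), sub[value].astype(float)))
    return out


def read_trna_table(path: str | Path) -> dict[str, TRNAProfile]:
    """TSV ``anticodon  abundance`` (+ optional ``sample``) → profiles."""
    df = _read_tsv(path, ["anticodon", "abundance"])
    return {
        s: TRNAProfile(s, vals)
        for s, vals in _by_sample(df, path, "anticodon", "abundance", Path(path).stem).items()
    }


def write_trna_table(profiles: Sequence[TRNAProfile], path: str | Path) -> None:
    rows = [
        {"anticodon": a, "abundance": repr(float(v)), "sample": p.sample_id}
        for p in profiles
        for a, v in sorted(p.abundance.items())
    ]
    pd.DataFrame(rows, columns=["anticodon", "abundance", "sample"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_table(path: str | Path) -> dict[str, ExpressionProfile]:
    """TSV ``gene_id  tpm`` (+ optional ``sample``) → profiles."""
    df = _read_tsv(path, ["gene_id", "tpm"])
    return {
        s: ExpressionProfile(s, vals)
        for s, vals in _by_sample(df, path, "gene_id", "tpm", Path(path).stem).items()
    }


def write_expression_table(
    profiles: Sequence[ExpressionProfile], path: str | Path
) -> None:
    rows = [
        {"gene_id": g, "tpm": repr(float(v)), "sample": p.sample_id}
        for p in profiles
        for g, v in sorted(p.tpm.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "tpm", "sample"]).to_csv(
        path, sep="\t", index=False
    )


def read_positional_trna(
    path: str | Path, codon_order_path: str | Path, sample_id: str | None = None
) -> TRNAProfile:
    """Read a positional 64-value abundance list (classic tAI convention).

    ``codon_order_path`` must list the 64 codons, one per line, in the
    exact order of the values; abundances are re-keyed to the anticodon
    that Watson–Crick pairs each listed codon.  The manifest checksum is
    logged so any reordering is traceable.
    """
    order = [
        line.strip().upper()
        for line in Path(codon_order_path).read_text().splitlines()
        if line.strip()
    ]
    if sorted(order) != sorted(ALL_CODONS):
        raise ValueError(
            f"{codon_order_path}: manifest must list each of the 64 codons exactly once"
        )
    logger.info(
        "codon-order manifest %s sha256=%s", codon_order_path, codon_order_checksum(order)
    )
    values = [
        float(line) for line in Path(path).read_text().split() if line.strip()
    ]
    if len(values) != 64:
        raise ValueError(f"{path}: expected 64 values, found {len(values)}")
    abundance = {
        codon_to_anticodon(c): v for c, v in zip(order, values) if v > 0
    }
    return TRNAProfile(sample_id or Path(path).stem, abundance)


# -------------------------------------------------------- SDAw matrices


def write_sdaw_matrix(matrix: SDAMatrix, path: str | Path) -> None:
    """Rows = codons (lexicographic), columns = samples."""
    df = matrix.values.T.sort_index()
    df.index.name = "codon"
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_sdaw_matrix(
    path: str | Path, condition: Mapping[str, str] | None = None
) -> SDAMatrix:
    df = pd.read_csv(path, sep="\t", index_col="codon", float_precision="round_trip")
    df = df.T
    df.columns.name = None
    df.index.name = None
    return SDAMatrix(df, dict(condition) if condition else None)


def read_conditions(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ["sample", "condition"])
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))


def write_conditions(conditions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(conditions.items()), columns=["sample", "condition"]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------- result files


def write_gene_scores(scores: Sequence[GeneScore], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": s.gene_id, "score": repr(float(s.score)), "kind": s.kind.value} for s in scores],
        columns=["gene_id", "score", "kind"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_scores(path: str | Path) -> list[GeneScore]:
    df = _read_tsv(path, ["gene_id", "score", "kind"])
    return [
        GeneScore(str(r.gene_id), float(r.score), ScoreKind(r.kind))
        for r in df.itertuples()
    ]


def write_differential_results(
    results: Sequence[DifferentialResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "codon": r.codon,
                "effect": repr(float(r.effect)),
                "direction": r.direction.value,
                "p": repr(float(r.p)),
                "q": repr(float(r.q)),
            }
            for r in results
        ],
        columns=["codon", "effect", "direction", "p", "q"],
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "es": repr(float(r.es)),
                "p": repr(float(r.p)),
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ],
        columns=["set_id", "es", "p", "n_perm", "seed"],
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ GMT


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT gene sets: set_id → (description, member genes)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT lines need set id, description and >= 1 gene"
            )
        set_id, description, genes = parts[0], parts[1], parts[2:]
        if set_id in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        sets[set_id] = (description, frozenset(g for g in genes if g))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(
    sets: Mapping[str, tuple[str, frozenset[str]]], path: str | Path
) -> None:
    lines = [
        "\t".join([set_id, desc, *sorted(genes)])
        for set_id, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Serialize a synthetic cohort into a directory of standard files.

    Writes cds.fasta, trna.tsv, expression.tsv, conditions.tsv and the
    simulation truth as truth.json — the exact formats the pipeline reads
    back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta_cds(cohort.cds, outdir / "cds.fasta")
    write_trna_table(cohort.trna, outdir / "trna.tsv")
    write_expression_table(cohort.expression, outdir / "expression.tsv")
    write_conditions(cohort.conditions, outdir / "conditions.tsv")
    (outdir / "truth.json").write_text(cohort.truth.to_json() + "\n")


def read_cohort(indir: str | Path) -> SyntheticCohort:
    indir = Path(indir)
    cds = read_fasta_cds(indir / "cds.fasta", mode="strict")
    trna = read_trna_table(indir / "trna.tsv")
    expression = read_expression_table(indir / "expression.tsv")
    conditions = read_conditions(indir / "conditions.tsv")
    truth = SimConfig.from_json((indir / "truth.json").read_text())
    order = sorted(conditions)
    return SyntheticCohort(
        cds,
        [expression[s] for s in order],
        [trna[s] for s in order],
        conditions,
        truth,
    )
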