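"""Multi-sample analyses over SDAw matrices.

PCA of sample × codon SDAw (with marker-gene correlation of the
components), per-codon two-condition differential testing with
Benjamini–Hochberg control, a weighted Kolmogorov–Smirnov pre-ranked
enrichment statistic for gene rankings (ΔSDA or RCU), and cross-cohort
consistency counting of differential hits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .sda import GeneScore, SDAProfile

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "Direction",
    "EnrichmentResult",
    "PCAResult",
    "SDAMatrix",
    "correlate_component",
    "count_consistent_changes",
    "differential_codon_test",
    "pca_sda",
    "preranked_enrichment",
]


@dataclass
class SDAMatrix:
    """Samples × codons SDAw with optional condition labels.

    After reconciliation (codons kept only if defined for every sample)
    the matrix has no missing cells.
    """

    values: pd.DataFrame
    condition: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("SDAw matrix contains missing cells")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("SDAw matrix contains non-positive values")
        if self.condition is not None:
            missing = set(self.values.index) - set(self.condition)
            if missing:
                raise ValueError(f"samples without condition label: {sorted(missing)}")

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[SDAProfile],
        condition: Mapping[str, str] | None = None,
    ) -> "SDAMatrix":
        if not profiles:
            raise ValueError("no profiles given")
        common = set(profiles[0].sdaw)
        for p in profiles[1:]:
            common &= set(p.sdaw)
        codons = sorted(common)
        if not codons:
            raise ValueError("no codon defined in every profile")
        df = pd.DataFrame(
            [[p.sdaw[c] for c in codons] for p in profiles],
            index=[p.sample_id for p in profiles],
            columns=codons,
        )
        cond = dict(condition) if condition is not None else None
        return cls(df, cond)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PCAResult:
    """PCA of a log2 SDAw matrix with a deterministic sign convention."""

    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # components × codons
    explained_variance_ratio: np.ndarray
    codon_means: pd.Series  # per-codon log2 means (for reconstruction)
    degenerate: bool = False


def pca_sda(matrix: SDAMatrix, n_components: int | None = None) -> PCAResult:
    """PCA on log2-transformed, per-codon-centered SDAw.

    No unit-variance scaling is applied, so high-variance codons drive
    the components.  Sign convention: within each component the
    largest-|loading| codon is made positive, which fixes the otherwise
    arbitrary orientation.  An all-constant matrix yields a flagged
    degenerate result rather than an error.
    """
    n_samples, n_codons = matrix.values.shape
    if n_samples < 3 or n_codons < 2:
        raise ValueError("PCA needs at least 3 samples and 2 codons")
    if n_components is None:
        n_components = min(n_samples - 1, n_codons)
    if n_components > min(n_samples, n_codons):
        raise ValueError(
            f"cannot extract {n_components} components from a "
            f"{n_samples}×{n_codons} matrix"
        )
    X = np.log2(matrix.values.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    means = pd.Series(X.mean(axis=0), index=matrix.codons)
    if np.allclose(X, X.mean(axis=0), atol=1e-12):
        logger.warning("SDAw matrix has zero variance; returning degenerate PCA")
        return PCAResult(
            scores=pd.DataFrame(0.0, index=matrix.samples, columns=comp_names),
            loadings=pd.DataFrame(0.0, index=comp_names, columns=matrix.codons),
            explained_variance_ratio=np.zeros(n_components),
            codon_means=means,
            degenerate=True,
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=matrix.codons),
        explained_variance_ratio=pca.explained_variance_ratio_,
        codon_means=means,
    )


def correlate_component(
    scores_component: Mapping[str, float] | pd.Series,
    marker: Mapping[str, float],
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlate one PCA component with a per-sample marker (e.g. Ki67).

    Spearman by default (robust on the log-ratio scale), Pearson
    optional.  Constant inputs have no defined correlation and return
    (nan, nan) with a warning.
    """
    sc = dict(scores_component)
    shared = [s for s in sc if s in marker]
    if len(shared) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.array([sc[s] for s in shared], dtype=float)
    y = np.array([marker[s] for s in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return (float(r), float(p))


class Direction(str, Enum):
    FAVORED_IN_A = "FAVORED_IN_A"
    FAVORED_IN_B = "FAVORED_IN_B"


@dataclass(frozen=True)
class DifferentialResult:
    """Two-condition differential SDAw test result for one codon."""

    codon: str
    effect: float  # median SDAw(B) − median SDAw(A)
    direction: Direction
    p: float
    q: float


def differential_codon_test(
    matrix: SDAMatrix,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> list[DifferentialResult]:
    """Per-codon two-sided test of SDAw between two conditions.

    Wilcoxon rank-sum (Mann–Whitney U) by default, robust on the ratio
    scale; ``test="t"`` runs Welch's t on log SDAw instead.  P-values are
    Benjamini–Hochberg adjusted across the codons of the matrix; results
    are sorted by q, then by |effect| descending.
    """
    if matrix.condition is None:
        raise ValueError("matrix has no condition labels")
    groups = {cond_a: [], cond_b: []}
    for s in matrix.samples:
        lab = matrix.condition[s]
        if lab in groups:
            groups[lab].append(s)
    for lab, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"condition {lab!r} has {len(members)} sample(s); need >= 2")
    A = matrix.values.loc[groups[cond_a]]
    B = matrix.values.loc[groups[cond_b]]
    codons = matrix.codons
    pvals = np.empty(len(codons))
    effects = np.empty(len(codons))
    for i, c in enumerate(codons):
        x, y = A[c].to_numpy(), B[c].to_numpy()
        if test == "wilcoxon":
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            pvals[i] = res.pvalue
        elif test == "t":
            pvals[i] = stats.ttest_ind(
                np.log(x), np.log(y), equal_var=False
            ).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        effects[i] = np.median(y) - np.median(x)
    qvals = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    results = [
        DifferentialResult(
            codon=c,
            effect=float(effects[i]),
            direction=Direction.FAVORED_IN_B if effects[i] > 0 else Direction.FAVORED_IN_A,
            p=float(pvals[i]),
            q=float(qvals[i]),
        )
        for i, c in enumerate(codons)
    ]
    results.sort(key=lambda r: (r.q, -abs(r.effect), r.codon))
    return results


@dataclass(frozen=True)
class EnrichmentResult:
    """Pre-ranked enrichment result for one gene set."""

    set_id: str
    es: float
    p: float
    n_perm: int
    seed: int


def _running_es(weights: np.ndarray, hits: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n_miss = int((~hits).sum())
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores are exactly 0: fall back to equal steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    step = np.where(hits, hit_w / total, -1.0 / n_miss)
    run = np.cumsum(step)
    return float(run[int(np.argmax(np.abs(run)))])


def preranked_enrichment(
    scores: Sequence[GeneScore] | Mapping[str, float],
    gene_set: Iterable[str],
    *,
    set_id: str = "gene_set",
    n_perm: int = 999,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Weighted Kolmogorov–Smirnov enrichment of a gene set in a ranking.

    Genes are ranked by score descending (stable gene-id tiebreak).
    Walking down the ranking, in-set genes increment the running sum
    proportionally to |score|^weight_exponent and out-of-set genes
    decrement it uniformly; the enrichment score ES is the signed maximum
    deviation, bounded in [−1, 1].  Significance is by gene-label
    permutation: p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1), so
    p ≥ 1/(n_perm + 1) always.
    """
    if isinstance(scores, Mapping):
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    else:
        items = sorted(((s.gene_id, s.score) for s in scores), key=lambda kv: (-kv[1], kv[0]))
    if len(items) != len({g for g, _ in items}):
        raise ValueError("duplicate gene ids in ranking")
    genes = np.array([g for g, _ in items])
    vals = np.array([v for _, v in items], dtype=float)
    members = set(gene_set) & set(genes)
    n, n_hit = len(genes), len(members)
    if n_hit < 2:
        raise ValueError("gene set shares fewer than 2 genes with the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranking; no background remains")
    hits = np.isin(genes, sorted(members))
    w = np.abs(vals) ** weight_exponent
    es_obs = _running_es(w, hits)

    rng = np.random.default_rng(seed)
    # permute gene labels == place n_hit hits uniformly at random
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
    wsel = w[idx]
    totals = wsel.sum(axis=1)
    zero = totals == 0
    if zero.any():
        wsel[zero] = 1.0
        totals[zero] = n_hit
    miss_step = -1.0 / (n - n_hit)
    steps = np.full((n_perm, n), miss_step)
    np.put_along_axis(steps, idx, wsel / totals[:, None], axis=1)
    runs = np.cumsum(steps, axis=1)
    es_perm = np.take_along_axis(
        runs, np.argmax(np.abs(runs), axis=1)[:, None], axis=1
    ).ravel()
    p = (1 + int((np.abs(es_perm) >= abs(es_obs)).sum())) / (n_perm + 1)
    return EnrichmentResult(set_id=set_id, es=es_obs, p=float(p), n_perm=n_perm, seed=seed)


def count_consistent_changes(
    results_by_cohort: Mapping[str, Sequence[DifferentialResult]],
    codon: str,
    alpha: float = 0.05,
) -> tuple[int, int, int]:
    """Count cohorts where a codon is significantly shifted, per direction.

    Returns (n significant favored-in-A, n significant favored-in-B,
    n cohorts in which the codon was tested).  Cohorts whose results do
    not cover the codon are flagged and excluded from the denominator —
    this reproduces "X out of Y cancer types" style summaries.
    """
    if not results_by_cohort:
        raise ValueError("no cohorts given")
    n_a = n_b = tested = 0
    for cohort, results in results_by_cohort.items():
        hit = next((r for r in results if r.codon == codon), None)
        if hit is None:
            logger.warning("cohort %s: codon %s not tested; excluded", cohort, codon)
            continue
        tested += 1
        if hit.q < alpha:
            if hit.direction is Direction.FAVORED_IN_A:
                n_a += 1
            else:
                n_b += 1
    return (n_a, n_b, tested)
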