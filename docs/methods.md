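# Methods

## Pairing rules and supply weights

The codon–anticodon interaction model is the tAI wobble scheme. Each of
the 61 sense codons has exactly one Watson–Crick decoder (the reverse
complement of the codon, penalty s = 0) and, depending on its third
base, at most one wobble decoder:

| codon 3rd base | wobble anticodon 34 | pair class | default s |
| --- | --- | --- | --- |
| T | G | G34:U3 | 0.41 |
| C | A (read as inosine) | I34:C3 | 0.28 |
| A | A (read as inosine) | I34:A3 | 0.9999 |
| A | C (lysidine; prokaryotes only, off by default) | C34:A3 | 0.89 |
| G | T | U34:G3 | 0.68 |

Decoding efficiency is 1 − s. The defaults are the standard tAI
selective constraints; they are configuration (`SParams`), not
hard-coded truth. One restriction applies in strict mode (default): a
U34:G3 rule is suppressed when the donor anticodon's cognate codon
(NNA) is a stop or codes a different amino acid, which removes exactly
the ATG and TGG wobble rules — both codons keep only their Watson–Crick
decoder, matching reference tAI behavior. Inosine rules are exempt from
this restriction, as in the reference scheme. With eukaryotic defaults
the table has 120 rules (61 WC + 16 G34:U3 + 16 I34:C3 + 14 I34:A3 +
13 U34:G3).

Everything is keyed by codon/anticodon string. The rule set is an
unordered collection; the only positional interface in the package is
the explicit-manifest adapter in `sdatools.io`, which requires a
64-codon order file and logs its SHA-256 checksum. This design exists
because positional tAI input vectors are a documented source of silent
stop-codon misplacement bugs.

Supply weights sum decoder abundances times efficiency. Codons with no
observed decoder (W = 0) are imputed with the geometric mean of the
non-zero weights before normalization — the reference tAI convention,
without which the downstream geometric means would collapse to zero —
and the imputation can be disabled (`impute_zeros=False`). Anticodons
present in a profile but absent from the rule table raise by default
(they usually indicate a mislabeled table) and can be ignored
explicitly. Missing decoder anticodons count as abundance zero and are
logged.

## SDAw, gene SDA, ΔSDA

Supply and demand are both sum-to-one relative frequencies over the 61
sense codons; SDAw is their elementwise ratio. This fraction-ratio form
is a reconstruction: it reproduces the documented balance point
(SDAw = 1 when supply matches demand) and works with the standard
favored (> 2) / disfavored (< 0.5) thresholds, but the original
normalization is not restated in the source material — treat absolute
SDAw values from other implementations as comparable only up to
normalization convention. Thresholds are strict inequalities: 2.0 and
0.5 classify as balanced.

Codons with zero demand (possible in tiny CDS sets) have no defined
SDAw; they are dropped with a warning rather than reported as infinite.
Gene SDA is computed in log space — exp(mean(log SDAw)) over the gene's
codon occurrences, stop codons never included — so it is exactly the
geometric mean and numerically stable for long genes. For ΔSDA between
sample cohorts, each condition is first summarized by the arithmetic
mean of its samples' SDAw per codon, then gene scores are differenced;
output is sorted descending with a stable gene-id tiebreak.

## Cohort statistics

*PCA* operates on log2 SDAw with per-codon centering and no
unit-variance scaling, so high-variance codons drive the components.
Component signs are fixed by making the largest-|loading| codon of each
component positive. An all-constant matrix returns a flagged degenerate
result. *Marker correlation* is Spearman by default (robust on the
log-ratio scale), Pearson optional; constant inputs return NaN with a
warning rather than a fabricated coefficient.

*Differential testing* is a two-sided Wilcoxon rank-sum per codon
(robust for ratio-scale SDAw; Welch's t on log SDAw available), with
Benjamini–Hochberg adjustment across the codons of the matrix and
effect = median SDAw(B) − median SDAw(A). Tests are unpaired; a paired
variant is deliberately not claimed. Cross-cohort consistency counts,
per direction, the cohorts in which a codon is significant at the given
alpha; cohorts that did not test the codon are excluded from the
denominator.

*Pre-ranked enrichment* is the weighted Kolmogorov–Smirnov running-sum
statistic: genes ranked by score descending, in-set genes increment by
|score|^w / Σ|score|^w (w = 1 by default), out-of-set genes decrement
by 1/(#misses), ES = signed maximum deviation (bounded in [−1, 1]).
Significance is by gene-label permutation with a mandatory seed
recorded in the result: p = (1 + #{|ES⊥| ≥ |ES|}) / (n_perm + 1), so
p is never zero and never below 1/(n_perm + 1). If every in-set score
is exactly zero the hit increments fall back to equal steps.

## Synthetic cohorts

The generator emulates the statistical structure of a two-condition
bulk study:

- **CDS sets** — genes start ATG, end with one stop, no internal stops;
  synonymous-codon choices are family-wise Dirichlet-multinomial
  (concentration 5 by default, a moderate codon-usage bias); lengths are
  Poisson around 300 codons (floor 3). 200 genes by default.
- **Expression** — per-gene log-normal baseline (log-mean 3, log-sd 1,
  TPM-like scale) shared by all samples.
- **tRNA repertoires** — the anticodon universe is the decoder side of
  the pairing-rule table (61 anticodons), so any planted supply effect
  has a carrier; baseline log-normal spread 0.5 across anticodons.
- **Noise** — multiplicative log-normal, log-sd 0.25 (~28% coefficient
  of variation), applied independently to every anticodon abundance and
  every gene's expression in every sample. Chosen as the simplest
  heavy-tailed positive noise model; it is a stand-in, not an estimate
  of real assay noise.
- **Planted condition effects** — a SUPPLY effect multiplies the
  *cognate* (Watson–Crick) anticodon of the planted codon in condition
  B by the fold change. This is the isoacceptor-overexpression
  mechanism (e.g. tRNA-Arg-TCT driving AGA); wobble-neighbor codons
  move only through the pairing rules, as in a real repertoire.
  Perturbing *all* decoder anticodons instead was rejected: doubling an
  inosine decoder also doubles the Watson–Crick supply of its own
  cognate codon, producing several equally significant hits and making
  "the planted codon is the top hit" unrecoverable by any test. A
  DEMAND effect tilts expression toward codon-rich genes:
  tpm_g ← tpm_g · fold^(f_g / mean f), with f_g the gene's frequency of
  the planted codon.
- **Latent factor** — an optional per-sample N(0, 1) proliferation-like
  factor scales the cognate anticodons of a configured codon subset by
  2^(strength · f) and the marker gene (MKI67 by default) by
  e^(marker_effect · f). The draw is recorded in the cohort
  (`factor_values`), and `planted_variance_share` reports the fraction
  of the cohort's log2-SDAw variance explained by the true factor (the
  variance of the best factor-aligned rank-1 approximation, which PC1
  always matches or exceeds).

All randomness flows through numpy PCG64 generators seeded from the
single configured seed via fixed stream ids, so a fixed seed yields
byte-identical serialized cohorts across platforms and runs.

What passing tests on these cohorts show: the pipeline recovers planted
supply/demand imbalances at realistic noise, its differential and
enrichment tests are calibrated under the null, and its PCA recovers a
planted covariance axis. What they do not show: performance on real
tRNA quantifications (modification-induced misincorporation, fragment
bias, isodecoder ambiguity), real codon-usage covariation across genes,
or any claim about effect sizes in real tissues.

## Problem sizes and numerical choices

Simulation-based checks use cohorts of 80–200 genes of 100–300 codons
and 3–20 samples per condition, with 10–100 replicate seeds per
property — sizes at which every planted effect is comfortably
detectable while the full suite runs in a few minutes. Tolerances:
sum-to-one normalization and the balance identity hold to 1e−9; PCA
reconstruction to 1e−8; classification boundaries are exact. Ties in
rankings break by gene id (ascending) for determinism. Degenerate
inputs (all-zero profiles, empty gene intersections, stop codons where
sense codons are required, constant matrices) raise or flag explicitly
rather than returning silent values.

## Known limitations

- The SDAw normalization is a documented reconstruction (see above).
- Mitochondrial and non-standard genetic codes, isodecoder-level
  modeling, codon-pair effects and ribosome kinetics are out of scope.
- The enrichment permutation scheme permutes gene labels, not codon
  positions; it tests set membership against the ranking, nothing more.
- Whether healthy/tumor comparisons should be paired is data-dependent;
  only the unpaired test is implemented.
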