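# Methods

This note documents the statistical models behind each pipeline stage,
the synthetic-data generator's assumptions, and the numerical choices made
where the design was genuinely open.

## Study design and data model

The pipeline targets a common-garden RNA-seq experiment with a two-factor
design: elevational zone of landrace origin (lowland, midland, highland;
five landraces each) crossed with field block (1–3), giving
3 × 5 × 3 = 45 libraries. Counts are gene × sample integers; metadata
carries landrace, zone and block per library. Sample order in the
metadata must match the count-matrix header exactly — a mismatch is an
error rather than a silent reorder, because silent matching has no
defence against duplicated or renamed libraries. All-zero genes are kept
at ingest; each analysis stage excludes them explicitly, so the record of
what was filtered lives with the analysis, not the file reader.

## Normalization

Size factors use the median-of-ratios estimator: with
g_i = (∏_j K_ij)^{1/n} the geometric mean of gene i across samples,

  s_j = median over genes i with all-positive counts of K_ij / g_i.

The geometric mean is computed in log space to avoid overflow; the median
is taken on the ratio scale (taking it in log space changes the result
whenever the number of reference genes is even). The estimator assumes
most genes are not differentially expressed; simulations with planted
depth factors recover them to within 5% at 2,000 genes.

The variance-stabilizing transform used before clustering is
`log2(x + 1)`: monotone, zero-preserving, and sufficient for
correlation-distance clustering, which depends only on rank/linear
structure. This is a deliberate simplification relative to the parametric
variance-stabilizing transforms fitted by dedicated DE packages; it is
not claimed to equal them.

## Differential expression

Per gene, counts follow a negative-binomial GLM with log link:

  log μ_ij = log s_j + β₀ + block_j + zone_j,   Var(K) = μ + α μ².

- **Dispersion.** α̂_i = max(0, (v_i − m_i)/m_i²), with m_i the mean
  normalized count and v_i the *pooled within-cell* variance over
  zone × block cells (so planted zone and block effects do not inflate
  the estimate). Gene-wise estimates are then shrunk 50/50 toward a
  lowess trend of α̂ against log₁₀ mean (frac = 0.5, clipped at 0). The
  50/50 blend is a fixed, transparent stand-in for the inverse-variance
  empirical-Bayes shrinkage of full DE tools.
- **Fitting.** Iteratively reweighted least squares, batched across genes
  (the design matrix is shared; only the working weights differ), working
  weight μ/(1 + αμ), linear predictor clipped to ±30, maximum 50
  iterations, relative-deviance tolerance 1e-8. Genes that fail to
  converge are flagged, their p set missing and excluded from the FDR
  denominator with a logged count. The fit agrees with an independent
  single-gene GLM implementation to ~1e-5 in coefficients and standard
  errors on test fixtures.
- **Contrasts.** For zones (a, b) the Wald statistic is c'β̂ / √(c'Σ̂c)
  with c the zone-dummy difference vector; two-sided p from the standard
  normal; log2fc = c'β̂ / ln 2, positive meaning higher expression in the
  first-named zone. The three pairwise contrasts reuse one fitted model,
  so log2fc(H,L) = log2fc(H,M) + log2fc(M,L) holds exactly at the
  coefficient level.
- **FDR.** Benjamini–Hochberg step-up per contrast; DE at FDR ≤ 0.05
  (inclusive boundary). Deliberately omitted relative to full DE tools:
  fold-change shrinkage, Cook's-distance outlier filtering, independent
  filtering, and the split-plot error structure (block enters as a fixed
  additive effect). These omissions trade exactness-at-the-margins for
  transparency; the package's guarantees are therefore stated as
  simulation-based error control (type-I fraction ≤ 0.05 under the null,
  ≥ 80% power at planted log2fc = 2, n = 15 vs 15, α = 0.1) rather than
  bit-level agreement with any external tool. No minimal-count pre-filter
  is applied beyond all-zero removal; callers can filter upstream.

## Expression-matched enrichment

Candidate gene sets for a biosynthesis pathway are concentrated at low
expression, so a naive over-representation test against all expressed
genes confounds pathway membership with expression level. The matching
procedure:

1. Mean normalized expression per candidate across all libraries;
   all-zero candidates dropped.
2. Ten **equal-width** bins spanning [min, max] of the candidate means
   (right-open intervals, last bin closed). Equal width, not equal
   occupancy: the two interpretations of "equally sized" diverge, and
   only equal width is consistent with a first bin holding ~89% of
   candidates while the bin boundaries advance in constant steps.
3. Bins whose lower edge exceeds 3,000 counts and which hold two or fewer
   candidates are dropped together with their genes (both thresholds are
   config knobs); remaining proportions renormalize.
4. The background universe for each comparison is the expressed-gene
   universe augmented (set union) with that comparison's DE genes and the
   candidate set. Background genes outside the candidate bin range are
   excluded — after augmentation, by default. Retained candidates are held
   out of the sampling pool and added back to the matched background, so
   the candidate-to-background ratio cell reflects candidates inside their
   own matched universe.
5. Matching is a **one-shot maximal allocation**: N is the largest integer
   whose largest-remainder quotas (floor(N·p_k) plus remainders by largest
   fractional part, ties by bin index) all fit the per-bin availability;
   quota genes are drawn uniformly without replacement with a stated seed.
   This realizes "subsample until the proportions match" deterministically
   given the seed: the output proportions deviate from the candidate
   proportions by at most 1/N per bin.
6. A two-sample chi-square on bins × {candidate, matched} verifies the
   match (Yates correction only at 1 df, i.e. exactly two retained bins;
   empty bins dropped with a warning); a match requires p > 0.95. In
   practice the verification p is ≈ 1.
7. The enrichment test is a Yates-corrected chi-square (1 df) on the 2×2
   table whose **cells** are the list totals:
   [[candidates_DE, DE_total], [candidates_bg, bg_total]]. Using totals as
   cells rather than margins is statistically unconventional (the
   candidate counts are nested inside the totals) but is the construction
   under which the three published statistics for these comparisons are
   exactly recovered, verified against a brute-force implementation; it
   is therefore the default, documented as such. The conventional nested
   in/out × DE/not-DE construction is available via `nested=True` (CLI
   `--nested-table`).
8. The Yates correction term is `max(|O − E| − 0.5, 0)` — capped so a
   perfect-fit table scores exactly 0 (an uncapped sign-flip correction
   manufactures a positive statistic from tables that fit better than
   0.5 counts per cell).
9. "Enriched" requires p < 0.05 **and** a candidate rate among DE genes
   exceeding the background candidate rate; significant depletion is
   reported as not enriched.

## Consensus clustering

Libraries are clustered on one-minus-Spearman correlation distances
(average ranks for ties) with average linkage (UPGMA). Stability comes
from resampling genes: per iteration, ⌈0.8 · n_genes⌉ features are drawn
without replacement, libraries re-clustered at k, and co-membership
accumulated; since every iteration scores all libraries, the consensus
denominator is simply the iteration count. The final partition cuts an
average-linkage tree on (1 − consensus). Defaults follow the study
settings (k = 18, 1,000 iterations); the resampling unit (genes, at 80%
without replacement) is this package's documented choice, since the
original GUI tool does not specify its scheme. Tests use small k on
planted data where the truth is known. DE heat maps use one-minus-Pearson
gene distances, leaf-order rows from the gene dendrogram, and min–max
scale each row to [0, 1] (constant rows become 0.5 with a warning).

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

- 12,000 background genes and 190 candidates by default (tests and the
  bundled fixture use 2,000 + 190 so the full pipeline runs in seconds);
  45 libraries in the 3 × 5 × 3 design.
- Baseline means log-normal: log μ ~ N(4, 2) for background
  (median ≈ 55 counts, spanning ~4 orders of magnitude), N(2.5, 2) for
  candidates. The lower candidate baseline mirrors the real candidate
  set's concentration in the lowest expression bin and ensures the
  expression-matching step does real work in tests — an unmatched
  background would be confounded by expression level.
- Counts K_ij ~ NB(s_j · μ_i · 2^{x_ij}, α) with α = 0.1 by default
  (between-landrace biological variability within a zone), per-gene block
  effects N(0, 0.2²) in log2, and log-normal library depths (sd 0.3,
  geometric mean 1).
- DE genes are planted with probability 0.1 (background) and
  min(1, φ · 0.1) (candidates), φ the enrichment factor. Planted log2
  fold changes are N(0, 1.5) truncated to |lfc| ≥ 0.5. Each DE gene gets
  one of three zone patterns — highland-only (0.4), shared
  highland+midland (0.4), midland-only (0.2) — so highland and midland
  share part of their signature, as the real elevational cline suggests.
  The `paper_like_fixture` preset shifts the mix to 0.25/0.6/0.15 and
  raises the effect floor to |lfc| ≥ 1, reproducing the observed cluster
  topology in which lowland libraries split off first.
- All randomness flows from one seed; per-stage streams are derived
  deterministically, so outputs are byte-identical across reruns.

What the generator does **not** model: read-level noise (counts are drawn
directly), GC/length biases, correlated co-expression modules beyond the
planted zone structure, landrace-level random effects (landraces within a
zone are exchangeable), and the within-library pooling of three plants
(absorbed into the NB dispersion). Passing recovery tests therefore show
the pipeline's statistics behave correctly under the stated NB model —
not that any particular biological dataset satisfies that model.

## Numerical notes and limitations

- Degenerate inputs: no all-positive gene → normalization error advising
  pre-filtering; degenerate candidate expression range or an empty
  retained bin → enrichment error; zero-variance library → clustering
  error naming the library.
- The enrichment 2×2 uses list totals as cells by default (see above);
  switch to `nested=True` for the conventional construction when exact
  comparability with other over-representation tools matters.
- Bin-filter wording is ambiguous in the source procedure; it is read
  here as "drop sparse (≤ 2-gene) bins lying above 3,000 counts", with
  both the occupancy and count thresholds exposed as parameters.
- Wald p-values use the asymptotic normal; at very small counts they are
  approximate, which the simulation-based error-control tests bound in
  aggregate rather than per gene.
- Consensus clustering at k larger than the number of genuinely distinct
  groups drives between-group consensus toward 0 and can leave top-level
  tree ties; qualitative topology checks are run at small k.
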