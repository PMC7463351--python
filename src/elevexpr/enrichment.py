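"""Expression-distribution-matched candidate-gene enrichment.

Candidate gene sets (here, phenolic-compound biosynthesis enzymes) are
expression-biased: most sit in the low-count tail, so a naive enrichment
test against all expressed genes confounds pathway membership with
expression level.  The procedure here removes that confounder:

1. average normalized expression per candidate gene across all libraries;
   all-zero candidates dropped;
2. ten equal-width expression bins spanning the candidate range, with the
   candidate proportion per bin;
3. sparse high-expression bins (lower edge above 3,000 counts, two or fewer
   candidates) dropped together with their genes;
4. the background universe (expressed genes, augmented with each
   comparison's DE genes and the candidates themselves) is subsampled
   without replacement so its per-bin proportions match the candidate
   proportions — a one-shot largest-remainder allocation at the maximal
   feasible size;
5. a chi-square on the bins x {candidate, matched} contingency verifies the
   match (requires p > 0.95);
6. the enrichment itself is a Yates-corrected chi-square on the 2x2 table
   whose cells are (candidates DE, total DE) vs (candidates in background,
   background size) — the construction that reproduces the published
   statistics; the conventional nested in/out construction is available via
   ``nested=True``.

The Yates correction is ``(|O - E| - 0.5)`` with the subtraction capped at
``|O - E|`` so a perfect-fit table scores exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression summaries and binning


def mean_expression(
    normalized: pd.DataFrame, genes: GeneSet | set[str] | None = None
) -> pd.Series:
    """Arithmetic mean normalized count per gene across all samples.

    ``normalized`` is genes x samples with gene IDs as index.  If ``genes``
    is given, restrict to those (error listing any missing IDs).
    """
    if genes is not None:
        ids = genes.sorted() if isinstance(genes, GeneSet) else sorted(genes)
        missing = [g for g in ids if g not in normalized.index]
        if missing:
            raise EnrichmentError(
                f"{len(missing)} genes absent from the matrix: {missing[:10]}"
            )
        normalized = normalized.loc[ids]
    return normalized.mean(axis=1)


def drop_unexpressed(means: pd.Series) -> pd.Series:
    """Remove genes whose average normalized count is zero."""
    kept = means[means > 0]
    n_dropped = len(means) - len(kept)
    if n_dropped:
        logger.info("%d genes with no expression excluded", n_dropped)
    return kept


@dataclass
class BinScheme:
    """Equal-width expression bins over the candidate mean-expression range."""

    n_bins: int
    edges: np.ndarray                    # length n_bins + 1, strictly ascending
    candidate_counts: np.ndarray         # occupancy per bin (retained bins)
    gene_bins: pd.Series                 # candidate gene -> bin index
    retained: np.ndarray = field(default=None)  # boolean mask over bins

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise EnrichmentError("bin edges must be strictly ascending")
        widths = np.diff(self.edges)
        if np.ptp(widths) > 1e-9 * max(1.0, widths.max()):
            raise EnrichmentError("bins must have equal widths")
        if self.retained is None:
            self.retained = np.ones(self.n_bins, dtype=bool)

    @property
    def candidate_props(self) -> np.ndarray:
        """Candidate proportions over retained bins (sums to 1)."""
        c = self.candidate_counts[self.retained].astype(float)
        return c / c.sum()

    @property
    def n_candidates(self) -> int:
        return int(self.candidate_counts[self.retained].sum())

    def assign(self, means: pd.Series) -> pd.Series:
        """Bin arbitrary genes by this scheme; out-of-range genes get -1."""
        x = means.to_numpy(dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        width = self.edges[1] - self.edges[0]
        idx = np.floor((x - lo) / width).astype(int)
        idx = np.where(x == hi, self.n_bins - 1, idx)  # last bin right-closed
        idx = np.where((x < lo) | (x > hi), -1, idx)
        return pd.Series(idx, index=means.index)


def compute_bins(candidate_means: pd.Series, n_bins: int = 10) -> BinScheme:
    """Equal-width bins spanning [min, max] of the candidate means.

    Intervals are right-open except the last, which is right-closed, so
    every gene lands in exactly one bin.
    """
    x = candidate_means.to_numpy(dtype=float)
    if len(np.unique(x)) < n_bins:
        raise EnrichmentError(
            f"need at least {n_bins} distinct mean values, got {len(np.unique(x))}"
        )
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise EnrichmentError("degenerate expression range (max == min)")
    edges = np.linspace(lo, hi, n_bins + 1)
    scheme = BinScheme(
        n_bins=n_bins,
        edges=edges,
        candidate_counts=np.zeros(n_bins, dtype=int),
        gene_bins=pd.Series(dtype=int),
    )
    gene_bins = scheme.assign(candidate_means)
    counts = np.bincount(gene_bins.to_numpy(), minlength=n_bins)
    scheme.candidate_counts = counts
    scheme.gene_bins = gene_bins
    return scheme


def filter_bins(
    scheme: BinScheme,
    min_genes: int = 3,
    high_count_threshold: float = 3000.0,
) -> BinScheme:
    """Drop sparse high-expression bins and their genes.

    A bin is dropped when its lower edge exceeds ``high_count_threshold``
    and it holds fewer than ``min_genes`` candidates (i.e. two or fewer at
    the default).  Remaining proportions renormalize.
    """
    lower_edges = scheme.edges[:-1]
    drop = (lower_edges > high_count_threshold) & (
        scheme.candidate_counts < min_genes
    )
    retained = scheme.retained & ~drop
    if not retained.any():
        raise EnrichmentError("bin filtering removed every bin")
    kept_genes = scheme.gene_bins[
        scheme.gene_bins.map(lambda b: retained[b])
    ]
    n_removed = len(scheme.gene_bins) - len(kept_genes)
    if n_removed:
        logger.info(
            "bin filter: dropped %d bins, removed %d candidate genes",
            int(drop.sum()),
            n_removed,
        )
    counts = scheme.candidate_counts.copy()
    counts[~retained] = 0
    return BinScheme(
        n_bins=scheme.n_bins,
        edges=scheme.edges,
        candidate_counts=counts,
        gene_bins=kept_genes,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# background construction and matching


def build_background(
    universe: GeneSet | set[str],
    de_genes: set[str],
    candidates: GeneSet | set[str],
) -> set[str]:
    """Background universe for one comparison: expressed genes augmented
    with the comparison's DE genes and the candidate set."""
    uni = universe.gene_ids if isinstance(universe, GeneSet) else set(universe)
    cand = candidates.gene_ids if isinstance(candidates, GeneSet) else set(candidates)
    if not uni:
        raise EnrichmentError("empty background universe")
    bg = uni | set(de_genes) | cand
    logger.info("background universe: %d genes", len(bg))
    return bg


@dataclass
class MatchedBackground:
    """Seeded subsample of the background matched to the candidate bins."""

    gene_ids: list[str]
    per_bin_counts: np.ndarray
    total_n: int
    seed: int


def _largest_remainder(n: int, props: np.ndarray) -> np.ndarray:
    """Apportion n among bins by props: floors, then largest fractional parts."""
    exact = n * props
    quotas = np.floor(exact).astype(int)
    shortfall = n - quotas.sum()
    if shortfall > 0:
        frac = exact - quotas
        # ties broken by bin index (stable argsort on negated fractions)
        order = np.argsort(-frac, kind="stable")
        quotas[order[:shortfall]] += 1
    return quotas


def match_background(
    background_means: pd.Series,
    scheme: BinScheme,
    seed: int,
) -> MatchedBackground:
    """Subsample background genes so per-bin proportions match the candidates.

    Genes outside the candidate expression range are excluded first.  The
    total N is the largest integer whose largest-remainder quotas fit the
    per-bin availability; quota genes are drawn uniformly without
    replacement per bin.
    """
    bins = scheme.assign(background_means)
    n_outside = int((bins == -1).sum())
    if n_outside:
        logger.info("%d background genes outside the candidate bins excluded", n_outside)
    bins = bins[bins >= 0]
    bins = bins[bins.map(lambda b: scheme.retained[b])]

    retained_idx = np.where(scheme.retained)[0]
    props = scheme.candidate_props
    avail = np.array([(bins == b).sum() for b in retained_idx])
    empty = retained_idx[(avail == 0) & (props > 0)]
    if len(empty):
        raise EnrichmentError(
            f"no background genes available in retained bin(s) {empty.tolist()}"
        )

    # maximal N with feasible largest-remainder quotas
    with np.errstate(divide="ignore"):
        upper = np.min(
            np.where(props > 0, (avail + 1) / np.maximum(props, 1e-300), np.inf)
        )
    n = int(min(upper, bins.size))
    quotas = None
    while n > 0:
        q = _largest_remainder(n, props)
        if np.all(q <= avail):
            quotas = q
            break
        n -= 1
    if quotas is None:
        raise EnrichmentError("no feasible matched-background allocation")

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for b, quota in zip(retained_idx, quotas):
        pool = sorted(bins.index[bins == b])
        pick = rng.choice(len(pool), size=quota, replace=False)
        chosen.extend(pool[i] for i in sorted(pick))
    logger.info(
        "matched background: N=%d over %d bins (availability %s)",
        n,
        len(retained_idx),
        avail.tolist(),
    )
    return MatchedBackground(
        gene_ids=chosen, per_bin_counts=quotas, total_n=n, seed=seed
    )


def verify_match(
    candidate_counts: np.ndarray, matched_counts: np.ndarray
) -> tuple[float, float]:
    """Two-sample chi-square that the binned distributions agree.

    Contingency is bins x {candidate, matched}; bins with zero combined
    count are dropped with a warning; the Yates correction applies only
    when exactly two bins remain (1 df).  A successful match requires
    p > 0.95.
    """
    c = np.asarray(candidate_counts, dtype=float)
    m = np.asarray(matched_counts, dtype=float)
    if c.shape != m.shape:
        raise EnrichmentError("bin count vectors differ in length")
    if c.sum() <= 0 or m.sum() <= 0:
        raise EnrichmentError("both distributions must be non-empty")
    keep = (c + m) > 0
    if not keep.all():
        logger.warning("%d empty bins dropped from match verification", int((~keep).sum()))
        c, m = c[keep], m[keep]
    table = np.column_stack([c, m])
    return _contingency_chi2(table, yates=(table.shape[0] == 2))


# ---------------------------------------------------------------------------
# the enrichment test itself


def _contingency_chi2(table: np.ndarray, yates: bool) -> tuple[float, float]:
    O = np.asarray(table, dtype=float)
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if np.any(rows == 0) or np.any(cols == 0) or total == 0:
        raise EnrichmentError("contingency table has a zero margin")
    E = rows * cols / total
    dev = np.abs(O - E)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)  # capped: perfect fit scores 0
    stat = float(np.sum(dev**2 / E))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, p


def yates_chi2(
    candidate_de: int, de_total: int, candidate_bg: int, bg_total: int
) -> tuple[float, float]:
    """Yates-corrected chi-square on the published 2x2 construction.

    The four inputs are used directly as the table cells
    ``[[candidate_de, de_total], [candidate_bg, bg_total]]`` — the list
    totals enter as cells, not margins, which is the layout that reproduces
    the published comparison of the ratios candidate_de/de_total and
    candidate_bg/bg_total.  1 df; upper-tail p.
    """
    cells = np.array(
        [[candidate_de, de_total], [candidate_bg, bg_total]], dtype=float
    )
    if (cells < 0).any():
        raise EnrichmentError("counts must be non-negative")
    return _contingency_chi2(cells, yates=True)


def nested_yates_chi2(
    candidate_de: int, de_total: int, candidate_bg: int, bg_total: int
) -> tuple[float, float]:
    """Conventional 2x2: candidate in/out x DE in/out, Yates corrected.

    Cells: [[cand & DE, non-cand & DE], [cand & not DE, non-cand & not DE]].
    Requires candidate_de <= de_total and counts nested in the background.
    """
    if candidate_de > de_total or candidate_bg > bg_total or de_total > bg_total:
        raise EnrichmentError("nested construction requires nested counts")
    table = np.array(
        [
            [candidate_de, de_total - candidate_de],
            [candidate_bg - candidate_de, bg_total - de_total - (candidate_bg - candidate_de)],
        ],
        dtype=float,
    )
    if (table < 0).any():
        raise EnrichmentError("inconsistent nested counts")
    return _contingency_chi2(table, yates=True)


@dataclass
class EnrichmentResult:
    """One comparison's row of the enrichment summary."""

    comparison: str
    candidate_bg: int
    bg_total: int
    candidate_de: int
    de_total: int
    chi2: float
    p: float
    enriched: bool


def test_enrichment(
    comparison: str,
    candidate_de: int,
    de_total: int,
    candidate_bg: int,
    bg_total: int,
    alpha: float = 0.05,
    nested: bool = False,
) -> EnrichmentResult:
    """Enrichment call for one comparison.

    Enriched requires p < alpha AND the candidate rate among DE genes
    exceeding the candidate rate in the background (the test is two-sided;
    the direction rule screens out depletion).
    """
    fn = nested_yates_chi2 if nested else yates_chi2
    chi2, p = fn(candidate_de, de_total, candidate_bg, bg_total)
    over = (
        de_total > 0
        and bg_total > 0
        and candidate_de / de_total > candidate_bg / bg_total
    )
    return EnrichmentResult(
        comparison=comparison,
        candidate_bg=candidate_bg,
        bg_total=bg_total,
        candidate_de=candidate_de,
        de_total=de_total,
        chi2=chi2,
        p=p,
        enriched=bool(p < alpha and over),
    )


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Summary table, one row per pairwise comparison."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "background_ratio": [
                f"{r.candidate_bg}/{r.bg_total}" for r in results
            ],
            "de_ratio": [f"{r.candidate_de}/{r.de_total}" for r in results],
            "enriched": ["Yes" if r.enriched else "No" for r in results],
        }
    )


def run_enrichment(
    normalized: pd.DataFrame,
    candidates: GeneSet,
    universe: GeneSet,
    de_sets: dict[str, set[str]],
    n_bins: int = 10,
    min_genes: int = 3,
    high_count_threshold: float = 3000.0,
    alpha: float = 0.05,
    nested: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full matched-background enrichment over all pairwise comparisons.

    ``de_sets`` maps comparison name (e.g. ``"highland-lowland"``) to its DE
    gene IDs.  Returns the summary table and a details dict with the bin
    scheme, matched backgrounds and match-verification statistics.
    """
    cand_means = drop_unexpressed(
        mean_expression(normalized, candidates)
    )
    scheme = filter_bins(
        compute_bins(cand_means, n_bins=n_bins),
        min_genes=min_genes,
        high_count_threshold=high_count_threshold,
    )
    retained_candidates = set(scheme.gene_bins.index)

    results = []
    details: dict = {"scheme": scheme, "matched": {}, "match_check": {}}
    for i, (name, de_genes) in enumerate(de_sets.items()):
        bg = build_background(universe, de_genes, candidates)
        bg_means = mean_expression(
            normalized, {g for g in bg if g in normalized.index}
        )
        bg_means = bg_means[~bg_means.index.isin(retained_candidates)]
        matched = match_background(bg_means, scheme, seed=seed + i)
        chi2_m, p_m = verify_match(
            scheme.candidate_counts[scheme.retained], matched.per_bin_counts
        )
        details["matched"][name] = matched
        details["match_check"][name] = (chi2_m, p_m)

        matched_set = set(matched.gene_ids) | retained_candidates
        de_in_bg = de_genes & matched_set
        results.append(
            test_enrichment(
                name,
                candidate_de=len(de_genes & retained_candidates),
                de_total=len(de_in_bg),
                candidate_bg=len(retained_candidates),
                bg_total=matched.total_n + len(retained_candidates),
                alpha=alpha,
                nested=nested,
            )
        )
    return enrichment_report(results), details
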