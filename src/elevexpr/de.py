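"""Negative-binomial two-factor differential expression with Wald contrasts.

Per gene, counts are modelled as NB(mu_ij, alpha_i) with a log link,

    log mu_ij = log s_j + beta_0 + block_j + zone_j,

where s_j is the median-of-ratios size factor (a fixed offset), block is an
additive nuisance factor and zone of landrace origin carries the effects of
interest.  Gene-wise dispersions alpha_i are method-of-moments estimates on
normalized counts within zone x block cells, shrunk halfway toward a
mean--dispersion trend.  Pairwise zone contrasts are tested with Wald
statistics (coefficient difference over its standard error, two-sided
normal p), and p-values are Benjamini--Hochberg adjusted per contrast.

This is a transparent re-implementation of the standard NB GLM analysis:
no fold-change shrinkage, no outlier filtering, no independent filtering.
Fitting is iteratively reweighted least squares, batched across genes
(the design matrix is shared; only the working weights differ per gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests
from sklearn.base import BaseEstimator

from .io import CountMatrix, ZONES
from .normalization import estimate_size_factors, normalize

LN2 = np.log(2.0)

#: The three admissible pairwise zone contrasts, each reported "first over second".
PAIRWISE_CONTRASTS = (
    ("highland", "lowland"),
    ("highland", "midland"),
    ("midland", "lowland"),
)


class DEError(ValueError):
    pass


def _check_contrast(contrast: tuple[str, str]) -> tuple[str, str]:
    a, b = contrast
    if a not in ZONES or b not in ZONES or a == b:
        raise DEError(
            f"contrast must be two distinct zones from {ZONES}, got {contrast}"
        )
    return a, b


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions: raw moments, fitted trend, shrunk final."""

    alpha: np.ndarray       # final (shrunk) dispersion, >= 0, finite
    trend: np.ndarray       # fitted mean-dispersion trend, >= 0
    raw: np.ndarray         # gene-wise method-of-moments estimate
    mean: np.ndarray        # mean normalized count per gene


def estimate_dispersions(
    normalized: np.ndarray,
    zones: np.ndarray,
    blocks: np.ndarray,
    shrink: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments dispersions on normalized counts within factor cells.

    For each gene, the within-cell (zone x block) variance and the overall
    mean give ``alpha_hat = max(0, (var - mean) / mean^2)``; the gene-wise
    estimates are then shrunk ``shrink`` of the way toward a lowess trend of
    alpha against log mean.  Requires >= 2 replicates in every occupied cell.
    """
    X = np.asarray(normalized, dtype=float)
    zones = np.asarray(zones)
    blocks = np.asarray(blocks)
    cells = pd.Series([f"{z}/{b}" for z, b in zip(zones, blocks)])
    counts_per_cell = cells.value_counts()
    if (counts_per_cell < 2).any():
        bad = counts_per_cell[counts_per_cell < 2].index.tolist()
        raise DEError(f"cells with fewer than 2 replicates: {bad}")

    # pooled within-cell variance (removes zone and block signal from the
    # variance estimate), overall mean on the normalized scale
    n = X.shape[1]
    ss = np.zeros(X.shape[0])
    df = 0
    for cell in counts_per_cell.index:
        cols = (cells == cell).to_numpy()
        k = cols.sum()
        sub = X[:, cols]
        ss += sub.var(axis=1, ddof=1) * (k - 1)
        df += k - 1
    var_within = ss / df
    mean = X.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - mean) / mean**2
    raw = np.where(mean > 0, np.maximum(raw, 0.0), 0.0)
    raw = np.nan_to_num(raw, nan=0.0, posinf=0.0)

    # trend: lowess of raw alpha against log10 mean, clipped non-negative
    pos = mean > 0
    if pos.sum() >= 10:
        order = np.argsort(np.log10(mean[pos]))
        fitted = lowess(
            raw[pos][order],
            np.log10(mean[pos])[order],
            frac=0.5,
            return_sorted=False,
        )
        trend_pos = np.empty_like(fitted)
        trend_pos[order] = np.maximum(fitted, 0.0)
        trend = np.zeros_like(raw)
        trend[pos] = trend_pos
    else:
        trend = np.full_like(raw, np.median(raw[pos]) if pos.any() else 0.0)

    alpha = (1.0 - shrink) * raw + shrink * trend
    return DispersionEstimates(alpha=alpha, trend=trend, raw=raw, mean=mean)


def _design_matrix(zones: np.ndarray, blocks: np.ndarray):
    """Intercept + treatment-coded block and zone dummies.

    Reference levels: block 1 and the first zone present in ZONES order.
    Returns (X, column names).
    """
    zones = np.asarray(zones)
    blocks = np.asarray(blocks)
    zone_levels = [z for z in ZONES if z in set(zones)]
    block_levels = sorted(set(int(b) for b in blocks))
    cols = [np.ones(len(zones))]
    names = ["intercept"]
    for b in block_levels[1:]:
        cols.append((blocks.astype(int) == b).astype(float))
        names.append(f"block:{b}")
    for z in zone_levels[1:]:
        cols.append((zones == z).astype(float))
        names.append(f"zone:{z}")
    return np.column_stack(cols), names


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Residual deviance per gene; reduces to Poisson deviance at alpha=0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    out = np.empty(y.shape[0])
    a = alpha[:, None]
    pois = alpha <= 0
    if pois.any():
        out[pois] = 2.0 * np.sum(term1[pois] - (y[pois] - mu[pois]), axis=1)
    nb = ~pois
    if nb.any():
        r = 1.0 / a[nb]
        out[nb] = 2.0 * np.sum(
            term1[nb] - (y[nb] + r) * np.log((y[nb] + r) / (mu[nb] + r)), axis=1
        )
    return out


def _fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Batched IRLS for the NB log-link GLM with per-gene dispersion.

    Y is (genes, samples); X is the shared (samples, p) design; offset is
    log size factors.  Returns (beta, cov, converged) with beta (genes, p)
    and cov the per-gene (p, p) inverse Fisher information.
    """
    G, n = Y.shape
    p = X.shape[1]
    # init from weighted least squares on log counts
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)
    a = alpha[:, None]
    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    cov = np.full((G, p, p), np.nan)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a[idx] * mu)          # mu^2 / V(mu)
        z = (eta - offset[None, :]) + (Y[idx] - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, w, z)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # ridge fallback for singular working information
            XtWX_r = XtWX + 1e-8 * np.eye(p)[None, :, :]
            new_beta = np.linalg.solve(XtWX_r, XtWz[..., None])[..., 0]
        bad = ~np.all(np.isfinite(new_beta), axis=1)
        new_beta[bad] = beta[idx][bad]
        beta[idx] = new_beta

        eta = np.clip(beta[idx] @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = _nb_deviance(Y[idx], mu, alpha[idx])
        delta = np.abs(new_dev - dev[idx]) / (np.abs(new_dev) + 0.1)
        just_converged = delta < tol
        dev[idx] = new_dev
        converged[idx[just_converged]] = True
        active[idx[just_converged]] = False

    # covariance at the final estimate for every gene
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
    ok = np.linalg.matrix_rank(XtWX) == p if G == 1 else None  # noqa: F841
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX)
    return beta, cov, converged


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini--Hochberg step-up FDR adjustment.

    Missing (NaN) entries are passed through and excluded from the
    denominator.  Entries outside [0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise DEError("p-values outside [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def call_de(table: pd.DataFrame, threshold: float = 0.05) -> set[str]:
    """Genes with FDR <= threshold (inclusive boundary); may be empty."""
    if not 0 < threshold < 1:
        raise DEError(f"threshold must be in (0, 1), got {threshold}")
    called = set(table.index[table["fdr"] <= threshold])
    import logging

    logging.getLogger(__name__).info(
        "%d genes called DE at FDR <= %g", len(called), threshold
    )
    return called


class NegativeBinomialDE(BaseEstimator):
    """Two-factor (block + zone) NB differential expression, sklearn style.

    ``fit`` takes counts with sklearn orientation (n_samples, n_genes) plus
    the per-sample zone and block factors; ``results`` returns the Wald test
    table for any pairwise zone contrast from the single fitted model.

    Parameters
    ----------
    dispersion_shrink : float, default=0.5
        Weight of the mean-dispersion trend in the final dispersion
        (0 = raw gene-wise, 1 = pure trend).
    max_iter, tol : IRLS iteration cap and relative-deviance tolerance.
    fdr_threshold : float, default=0.05
        Inclusive FDR cutoff used by ``results(...)['called']``.

    Attributes
    ----------
    coef_ : ndarray (n_genes, p) fitted GLM coefficients (natural log scale).
    covariance_ : ndarray (n_genes, p, p) per-gene coefficient covariance.
    converged_ : boolean ndarray (n_genes,).
    dispersions_ : final per-gene NB dispersions.
    size_factors_ : per-sample median-of-ratios factors.
    base_mean_ : per-gene mean normalized count.
    """

    def __init__(
        self,
        dispersion_shrink: float = 0.5,
        max_iter: int = 50,
        tol: float = 1e-8,
        fdr_threshold: float = 0.05,
    ):
        self.dispersion_shrink = dispersion_shrink
        self.max_iter = max_iter
        self.tol = tol
        self.fdr_threshold = fdr_threshold

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, zones, blocks, size_factors=None, dispersions=None,
            gene_ids=None):
        """Fit the NB GLM to counts X of shape (n_samples, n_genes)."""
        X = np.asarray(X)
        if X.ndim != 2:
            raise DEError("X must be 2-D (samples x genes)")
        zones = np.asarray(zones)
        blocks = np.asarray(blocks)
        if len(zones) != X.shape[0] or len(blocks) != X.shape[0]:
            raise DEError("zones/blocks must align with the rows of X")
        Y = X.T.astype(float)  # genes x samples internally
        self.gene_ids_ = (
            list(gene_ids) if gene_ids is not None
            else [f"g{i}" for i in range(Y.shape[0])]
        )

        if size_factors is None:
            expressed = Y[np.all(Y > 0, axis=1)]
            if expressed.shape[0] == 0:
                raise DEError("no gene expressed in all samples; cannot normalize")
            size_factors = estimate_size_factors(Y.astype(np.int64))
        self.size_factors_ = np.asarray(size_factors, dtype=float)

        norm = normalize(Y.astype(np.int64), self.size_factors_)
        self.base_mean_ = norm.mean(axis=1)

        if dispersions is None:
            disp = estimate_dispersions(
                norm, zones, blocks, shrink=self.dispersion_shrink
            )
            self.dispersions_ = disp.alpha
            self.dispersion_fit_ = disp
        else:
            self.dispersions_ = np.asarray(dispersions, dtype=float)

        design, names = _design_matrix(zones, blocks)
        self.design_matrix_ = design
        self.design_names_ = names

        nonzero = Y.sum(axis=1) > 0
        self.fitted_mask_ = nonzero
        G, p = Y.shape[0], design.shape[1]
        self.coef_ = np.full((G, p), np.nan)
        self.covariance_ = np.full((G, p, p), np.nan)
        self.converged_ = np.zeros(G, dtype=bool)
        if nonzero.any():
            beta, cov, conv = _fit_nb_glm(
                Y[nonzero],
                design,
                self.dispersions_[nonzero],
                np.log(self.size_factors_),
                max_iter=self.max_iter,
                tol=self.tol,
            )
            self.coef_[nonzero] = beta
            self.covariance_[nonzero] = cov
            self.converged_[nonzero] = conv
        self.zone_levels_ = [z for z in ZONES if z in set(zones)]
        return self

    # ------------------------------------------------------------------
    def _contrast_vector(self, contrast: tuple[str, str]) -> np.ndarray:
        a, b = _check_contrast(contrast)
        for z in (a, b):
            if z not in self.zone_levels_:
                raise DEError(f"zone {z!r} not present in the fitted design")
        v = np.zeros(len(self.design_names_))
        for z, sign in ((a, 1.0), (b, -1.0)):
            name = f"zone:{z}"
            if name in self.design_names_:
                v[self.design_names_.index(name)] = sign
        return v

    def results(self, contrast: tuple[str, str]) -> pd.DataFrame:
        """Wald test table for one pairwise zone contrast.

        Columns: base_mean, log2fc (first zone over second), se, wald, p,
        fdr, called, converged.  Non-converged genes carry NaN p and are
        excluded from the BH denominator.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coef_")
        v = self._contrast_vector(contrast)
        est = self.coef_ @ v
        var = np.einsum("i,gij,j->g", v, self.covariance_, v)
        se = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = est / se
        p = 2.0 * stats.norm.sf(np.abs(wald))
        usable = self.converged_ & self.fitted_mask_ & np.isfinite(p)
        n_dropped = int((~usable).sum())
        p = np.where(usable, p, np.nan)
        fdr = bh_adjust(p)
        table = pd.DataFrame(
            {
                "base_mean": self.base_mean_,
                "log2fc": est / LN2,
                "se": se / LN2,
                "wald": wald,
                "p": p,
                "fdr": fdr,
                "called": fdr <= self.fdr_threshold,
                "converged": usable,
            },
            index=pd.Index(self.gene_ids_, name="gene_id"),
        )
        if n_dropped:
            import logging

            logging.getLogger(__name__).info(
                "contrast %s: %d genes excluded (all-zero or non-converged)",
                contrast,
                n_dropped,
            )
        return table

    def de_genes(self, contrast: tuple[str, str]) -> set[str]:
        table = self.results(contrast)
        return set(table.index[table["called"]])


def fit_de(
    counts: CountMatrix,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    contrast: tuple[str, str] = ("highland", "lowland"),
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: fit the two-factor NB model and test one contrast."""
    if not counts.samples:
        raise DEError("count matrix carries no sample metadata")
    model = NegativeBinomialDE(**kwargs)
    model.fit(
        counts.counts.T,
        zones=counts.zones(),
        blocks=counts.blocks(),
        size_factors=size_factors,
        dispersions=dispersions,
        gene_ids=counts.gene_ids,
    )
    return model.results(contrast)
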