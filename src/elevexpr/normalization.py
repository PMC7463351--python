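"""Median-of-ratios library-size normalization and a shifted-log transform.

Size factor for sample j: the median over reference genes i of
``K_ij / geomean_i``, where the reference is every gene with strictly
positive counts in all samples and ``geomean_i`` is that gene's geometric
mean across samples (computed in log space).  Dividing column j by s_j
equalizes sequencing depth without being driven by the handful of most
highly expressed genes.

The variance-stabilizing transform used for clustering is ``log2(x + 1)``:
monotone, zero-preserving, and sufficient for the rank / linear structure
that correlation-distance clustering consumes.  It is a deliberate
simplification of the parametric transforms that dedicated DE tools fit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import CountMatrix


class NormalizationError(ValueError):
    pass


def estimate_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample (column).

    Requires at least one gene with strictly positive counts in every
    sample; otherwise raises :class:`NormalizationError` advising
    pre-filtering.
    """
    K = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    K = np.asarray(K, dtype=float)
    if K.ndim != 2:
        raise NormalizationError("counts must be 2-D (genes x samples)")
    all_positive = np.all(K > 0, axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "pre-filter to expressed genes before normalization"
        )
    ref = K[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)  # log space: no overflow
    ratios = ref / np.exp(log_geo_mean)[:, None]
    return np.median(ratios, axis=0)


def normalize(counts: CountMatrix | np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Divide each sample column by its size factor."""
    K = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    sf = np.asarray(size_factors, dtype=float)
    if sf.ndim != 1 or sf.shape[0] != K.shape[1]:
        raise NormalizationError(
            f"{sf.shape} size factors for {K.shape[1]} samples"
        )
    if (sf <= 0).any():
        raise NormalizationError("size factors must be positive")
    return np.asarray(K, dtype=float) / sf[None, :]


def variance_stabilize(normalized: np.ndarray) -> np.ndarray:
    """Shifted log: ``log2(x + 1)``. Maps 0 to 0, preserves rank order."""
    X = np.asarray(normalized, dtype=float)
    if (X < 0).any():
        raise NormalizationError("negative entries cannot be log-transformed")
    return np.log2(X + 1.0)


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer for median-of-ratios depth normalization.

    Follows the sklearn orientation: ``X`` is (n_samples, n_genes), i.e. the
    transpose of the on-disk gene x sample matrix.

    Parameters
    ----------
    log : bool, default=False
        If True, additionally apply the ``log2(x + 1)`` variance-stabilizing
        transform after depth normalization.

    Attributes
    ----------
    size_factors_ : ndarray of shape (n_samples_fit,)
        Median-of-ratios scale per sample seen in ``fit``.
    """

    def __init__(self, log: bool = False):
        self.log = log

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.size_factors_ = estimate_size_factors(X.T)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = check_array(X, dtype=float)
        if X.shape[0] != self.size_factors_.shape[0]:
            raise NormalizationError(
                "transform rows must align with the samples seen in fit "
                "(size factors are per-sample)"
            )
        out = X / self.size_factors_[:, None]
        if self.log:
            out = variance_stabilize(out)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
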