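"""RPKM normalisation, expression filtering, z-scoring and PCA.

Estimator classes follow the scikit-learn convention and take ``X`` as
(n_samples, n_features) = samples x genes.  The module-level functions keep
the genomics convention of genes-as-rows DataFrames and delegate to the
estimators, so both styles stay in sync.

RPKM (reads per kilobase of exon model per million mapped reads) is computed
against the column sums of the analysed count matrix; the expression filter
keeps a gene when its RPKM exceeds the threshold (strictly) in at least the
given fraction of samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "RPKMNormalizer",
    "ExpressionFilter",
    "GeneStandardizer",
    "compute_rpkm",
    "filter_expressed",
    "zscore_rows",
    "pca_scores",
]


def _as_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


class RPKMNormalizer(TransformerMixin, BaseEstimator):
    """Scale raw counts to RPKM: 1e9 * count / (length_bp * library_size).

    Parameters
    ----------
    gene_lengths_bp : Series or 1-D array
        Exon-model length of each gene in bp.  When ``X`` is a DataFrame the
        lengths are aligned on its column names; a plain array must already
        be in column order.

    The library size of each sample is the row sum of its counts in the
    matrix being transformed, so the transform is stateless (fit only
    validates).
    """

    def __init__(self, gene_lengths_bp=None):
        self.gene_lengths_bp = gene_lengths_bp

    def _lengths_for(self, X) -> np.ndarray:
        if self.gene_lengths_bp is None:
            raise ValueError("gene_lengths_bp must be provided")
        if isinstance(self.gene_lengths_bp, pd.Series) and isinstance(X, pd.DataFrame):
            missing = X.columns.difference(self.gene_lengths_bp.index)
            if len(missing):
                raise ValueError(f"no annotated length for gene_ids: {sorted(missing)}")
            lengths = self.gene_lengths_bp.reindex(X.columns).to_numpy(float)
        else:
            lengths = np.asarray(self.gene_lengths_bp, dtype=float)
        n_feat = X.shape[1]
        if lengths.shape != (n_feat,):
            raise ValueError(
                f"gene_lengths_bp has {lengths.shape} entries for {n_feat} genes"
            )
        if np.any(lengths < 1):
            raise ValueError("gene lengths must be >= 1 bp")
        return lengths

    def fit(self, X, y=None):
        arr = _as_array(X)
        self._lengths_for(X)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        arr = _as_array(X)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("counts must be finite and nonnegative")
        lengths = self._lengths_for(X)
        libsize = arr.sum(axis=1)
        if np.any(libsize <= 0):
            bad = np.flatnonzero(libsize <= 0)
            names = list(X.index[bad]) if isinstance(X, pd.DataFrame) else bad.tolist()
            raise ValueError(f"zero library size for sample(s): {names}")
        rpkm = 1e9 * arr / (lengths[None, :] * libsize[:, None])
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(rpkm, index=X.index, columns=X.columns)
        return rpkm


class ExpressionFilter(SelectorMixin, BaseEstimator):
    """Keep genes whose RPKM exceeds ``threshold`` in >= ``min_fraction`` of samples.

    The threshold comparison is strict (> threshold); the sample-fraction
    comparison is inclusive (>= min_fraction).
    """

    def __init__(self, threshold: float = 4.0, min_fraction: float = 0.5):
        self.threshold = threshold
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction must be in [0, 1], got {self.min_fraction}")
        arr = _as_array(X)
        if arr.size == 0:
            raise ValueError("empty expression matrix")
        frac = (arr > self.threshold).mean(axis=0)
        self.support_ = frac >= self.min_fraction
        self.n_features_in_ = arr.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        logger.info(
            "expression filter retained %d/%d genes (RPKM > %g in >= %.0f%% of samples)",
            int(self.support_.sum()), arr.shape[1], self.threshold, 100 * self.min_fraction,
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class GeneStandardizer(TransformerMixin, BaseEstimator):
    """Per-gene z-scores across samples, with the sample (n-1) standard deviation.

    Genes with zero variance transform to all-zero columns (a warning is
    logged) rather than NaN.
    """

    def fit(self, X, y=None):
        arr = _as_array(X)
        if arr.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 samples")
        self.mean_ = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        self.constant_mask_ = sd == 0
        if self.constant_mask_.any():
            logger.warning(
                "%d constant gene(s) mapped to all-zero z-scores",
                int(self.constant_mask_.sum()),
            )
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        arr = _as_array(X)
        z = (arr - self.mean_[None, :]) / self.scale_[None, :]
        z[:, self.constant_mask_] = 0.0
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(z, index=X.index, columns=X.columns)
        return z


# ---------------------------------------------------------------------------
# genes-as-rows functional interface
# ---------------------------------------------------------------------------

def compute_rpkm(counts: pd.DataFrame, annotation: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """RPKM matrix from a genes x samples count matrix.

    ``annotation`` is either a DataFrame with ``gene_id``/``length_bp``
    columns or a Series of lengths indexed by gene_id.  Library size is the
    column sum of ``counts``.
    """
    if isinstance(annotation, pd.DataFrame):
        lengths = annotation.set_index("gene_id")["length_bp"]
    else:
        lengths = annotation
    norm = RPKMNormalizer(gene_lengths_bp=lengths.astype(float))
    return norm.fit(counts.T).transform(counts.T).T


def filter_expressed(
    rpkm: pd.DataFrame, threshold: float = 4.0, min_fraction: float = 0.5
) -> pd.Index:
    """Ordered gene_ids passing the expression filter on a genes x samples matrix."""
    sel = ExpressionFilter(threshold=threshold, min_fraction=min_fraction).fit(rpkm.T)
    return rpkm.index[sel.support_]


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores of a genes x samples matrix (n-1 SD; constant rows -> 0)."""
    return GeneStandardizer().fit_transform(expr.T).T


def pca_scores(
    z: pd.DataFrame, n_components: int
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples on a genes x samples matrix (typically of z-scores).

    Samples are observations; each gene is mean-centred across samples before
    the SVD (no re-scaling).  Returns sample scores, gene loadings and the
    variance-explained fractions, which are non-increasing and sum to <= 1.
    """
    n_genes, n_samples = z.shape
    if not 1 <= n_components <= min(n_genes, n_samples):
        raise ValueError(
            f"n_components must be in [1, {min(n_genes, n_samples)}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.T.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=z.columns, columns=comp_names)
    loadings_df = pd.DataFrame(pca.components_.T, index=z.index, columns=comp_names)
    return scores_df, loadings_df, pca.explained_variance_ratio_
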