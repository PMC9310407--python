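"""Per-gene two-group differential expression with Benjamini-Hochberg control.

The default statistic is a two-sided Welch (unequal-variance) t-test on
log2(RPKM + pseudocount); the log2 fold change is the difference of group
means on the same transformed scale (comparison minus reference).  Genes
with zero variance in both groups and equal means get p = 1 and fold change
0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ContrastSpec",
    "TwoGroupContrast",
    "bh_adjust",
    "contrast_test",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    With the p-values sorted ascending, q_(i) = min_{j >= i} p_(j) * m / j,
    capped at 1, and returned in the original order.  Ties are handled by a
    stable sort; the running minimum gives tied p-values the most favourable
    (largest-index) factor, as in the step-up definition.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"expected a 1-D p-value vector, got shape {p.shape}")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided Welch t-test per column: returns (delta_mean, p).

    ``a``/``b`` are (n_a, genes) and (n_b, genes).  Columns where both groups
    are constant get p = 1 when the means agree and p = 0 otherwise.
    """
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    delta = mb - ma
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), 0.0, p)
    return delta, p


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison over an ordered gene universe."""

    name: str
    reference: str
    comparison: str
    universe: tuple[str, ...] | None = None


class TwoGroupContrast(BaseEstimator):
    """Welch-t differential expression between two sample groups.

    Parameters
    ----------
    reference, comparison : str
        Group labels in ``y``; the log2 fold change is comparison minus
        reference.
    pseudocount : float, default 1.0
        Added before the log2 transform.
    log_transform : bool, default True
        Set False when ``X`` is already on a log scale.

    Attributes (after ``fit(X, y)`` with X = samples x genes)
    ----------
    log2_fc_, p_raw_, q_bh_ : ndarray per gene
    gene_ids_ : column names when X is a DataFrame
    """

    def __init__(
        self,
        reference: str,
        comparison: str,
        pseudocount: float = 1.0,
        log_transform: bool = True,
    ):
        self.reference = reference
        self.comparison = comparison
        self.pseudocount = pseudocount
        self.log_transform = log_transform

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != y.shape[0]:
            raise ValueError("X must be samples x genes with one label per sample")
        if arr.shape[1] == 0:
            raise ValueError("empty gene universe")
        masks = {}
        for role, label in (("reference", self.reference), ("comparison", self.comparison)):
            mask = y == label
            if mask.sum() < 2:
                raise ValueError(
                    f"{role} group '{label}' has {int(mask.sum())} samples; need >= 2"
                )
            masks[role] = mask
        vals = np.log2(arr + self.pseudocount) if self.log_transform else arr
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values after transform")
        delta, p = _welch(vals[masks["reference"]], vals[masks["comparison"]])
        self.log2_fc_ = delta
        self.p_raw_ = p
        self.q_bh_ = bh_adjust(p)
        self.n_reference_ = int(masks["reference"].sum())
        self.n_comparison_ = int(masks["comparison"].sum())
        self.gene_ids_ = (
            np.asarray(X.columns, dtype=object)
            if isinstance(X, pd.DataFrame)
            else np.asarray([f"g{i}" for i in range(arr.shape[1])], dtype=object)
        )
        return self

    def results_(self) -> pd.DataFrame:
        check_is_fitted(self, "log2_fc_")
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids_,
                "log2_fc": self.log2_fc_,
                "p_raw": self.p_raw_,
                "q_bh": self.q_bh_,
            }
        )


def contrast_test(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ContrastSpec,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Run a two-group contrast on a genes x samples expression matrix.

    ``sheet`` maps sample_id to group.  The BH adjustment runs over the
    contrast's gene universe (``spec.universe`` or all rows of ``expr``).
    Returns a ContrastTable DataFrame (gene_id, log2_fc, p_raw, q_bh) in
    universe order, with the contrast name in ``.attrs["contrast"]``.
    """
    if spec.universe is not None:
        universe = pd.Index(spec.universe)
        missing = universe.difference(expr.index)
        if len(missing):
            raise ValueError(f"universe gene(s) missing from expression matrix: {sorted(missing)}")
        expr = expr.loc[universe]
    groups = sheet.set_index("sample_id")["group"]
    missing_samples = expr.columns.difference(groups.index)
    if len(missing_samples):
        raise ValueError(f"sample(s) absent from sample sheet: {sorted(missing_samples)}")
    labels = groups.reindex(expr.columns).to_numpy(object)
    keep = np.isin(labels, [spec.reference, spec.comparison])
    est = TwoGroupContrast(
        reference=spec.reference,
        comparison=spec.comparison,
        pseudocount=pseudocount,
        log_transform=log_transform,
    ).fit(expr.T.to_numpy()[keep], labels[keep])
    table = est.results_()
    table["gene_id"] = expr.index.to_numpy(object)
    table.attrs["contrast"] = spec.name
    return table
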