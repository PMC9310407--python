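"""Gene classifiers built on pairwise contrast tables.

Two bespoke rules are implemented:

* **Reversal by treatment** (three contrasts over one gene universe):
  a gene is an aging DEG when the old-vehicle vs young contrast is
  significant at the aging FDR; it is *reverted* when, in addition, the
  treated-vs-vehicle contrast is nominally significant with the opposite
  fold-change sign and the treated-vs-young contrast is *not* nominally
  significant (old treated expression indistinguishable from young).

* **Genotype dependence** (wild-type and knockout treatment contrasts):
  treatment DEGs are called in the wild type at an FDR threshold; a DEG is
  *dependent* on the gene product ablated in the knockout when the same
  treatment contrast loses nominal significance in the knockout, and
  *independent* when it stays significant.

All threshold comparisons are strict, exactly as stated in the rules
(FDR < t, p < t, p > t); a knockout p equal to its threshold is resolved to
"dependent" with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ReversalThresholds",
    "DependenceThresholds",
    "ReversalClassifier",
    "DependenceClassifier",
    "classify_reversal",
    "classify_dependence",
    "summarize_partition",
]

REVERSAL_CATEGORIES = ("not_aging_deg", "aging_not_reverted", "reverted")
DEPENDENCE_CATEGORIES = ("not_deg", "dependent", "independent")


def _check_threshold(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must be in (0, 1), got {value}")


@dataclass(frozen=True)
class ReversalThresholds:
    fdr_set1: float = 0.1
    p_set2: float = 0.05
    p_set3: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr_set1", "p_set2", "p_set3"):
            _check_threshold(name, getattr(self, name))


@dataclass(frozen=True)
class DependenceThresholds:
    fdr_deg: float = 0.2
    p_ko: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr_deg", "p_ko"):
            _check_threshold(name, getattr(self, name))


def _aligned(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Index each ContrastTable by gene_id and require identical universes."""
    out, reference = {}, None
    for name, tbl in tables.items():
        need = {"gene_id", "log2_fc", "p_raw", "q_bh"}
        missing = need.difference(tbl.columns)
        if missing:
            raise ValueError(f"contrast table '{name}' lacks column(s): {sorted(missing)}")
        idx = pd.Index(tbl["gene_id"])
        if idx.has_duplicates:
            raise ValueError(f"contrast table '{name}' has duplicated gene_ids")
        if reference is None:
            reference = idx
        elif set(idx) != set(reference):
            diff = sorted(set(idx).symmetric_difference(reference))
            raise ValueError(
                f"gene universes differ between contrast tables "
                f"(symmetric difference, first 10): {diff[:10]}"
            )
        out[name] = tbl.set_index("gene_id").loc[reference]
    return out


class ReversalClassifier(BaseEstimator):
    """Three-contrast reversal-by-treatment gene classifier.

    ``fit(set1, set2, set3)`` takes ContrastTables oriented as:
    set1 = old-vehicle vs young, set2 = old-treated vs old-vehicle,
    set3 = old-treated vs young.  After fitting, ``calls_`` holds one row
    per gene with its category and aging direction, and ``labels_`` the
    category array.
    """

    def __init__(self, fdr_set1: float = 0.1, p_set2: float = 0.05, p_set3: float = 0.05):
        self.fdr_set1 = fdr_set1
        self.p_set2 = p_set2
        self.p_set3 = p_set3

    def fit(self, set1: pd.DataFrame, set2: pd.DataFrame, set3: pd.DataFrame):
        ReversalThresholds(self.fdr_set1, self.p_set2, self.p_set3)
        t = _aligned({"set1": set1, "set2": set2, "set3": set3})
        s1, s2, s3 = t["set1"], t["set2"], t["set3"]
        genes = s1.index

        aging = (s1["q_bh"] < self.fdr_set1).to_numpy()
        lfc1 = s1["log2_fc"].to_numpy()
        direction = np.where(aging, np.where(lfc1 > 0, "up", "down"), "none").astype(object)
        # a zero aging fold change with a passing FDR has no direction to revert
        no_sign = aging & (lfc1 == 0)
        if no_sign.any():
            logger.info(
                "%d aging DEG(s) with zero fold change kept as aging_not_reverted",
                int(no_sign.sum()),
            )
        opposes = np.sign(s2["log2_fc"].to_numpy()) == -np.sign(lfc1)
        zero_lfc2 = aging & (s2["p_raw"].to_numpy() < self.p_set2) & (
            s2["log2_fc"].to_numpy() == 0
        )
        if zero_lfc2.any():
            logger.info(
                "%d gene(s) with zero treatment fold change but p < %g kept as "
                "aging_not_reverted (no sign to oppose)",
                int(zero_lfc2.sum()), self.p_set2,
            )
        reverted = (
            aging
            & ~no_sign
            & (s2["p_raw"].to_numpy() < self.p_set2)
            & opposes
            & (s2["log2_fc"].to_numpy() != 0)
            & (s3["p_raw"].to_numpy() > self.p_set3)
        )
        category = np.where(
            ~aging, "not_aging_deg", np.where(reverted, "reverted", "aging_not_reverted")
        ).astype(object)

        calls = pd.DataFrame(
            {
                "gene_id": genes,
                "category": category,
                "aging_direction": direction,
                "log2_fc_set1": lfc1,
                "p_raw_set1": s1["p_raw"].to_numpy(),
                "q_bh_set1": s1["q_bh"].to_numpy(),
                "log2_fc_set2": s2["log2_fc"].to_numpy(),
                "p_raw_set2": s2["p_raw"].to_numpy(),
                "q_bh_set2": s2["q_bh"].to_numpy(),
                "log2_fc_set3": s3["log2_fc"].to_numpy(),
                "p_raw_set3": s3["p_raw"].to_numpy(),
                "q_bh_set3": s3["q_bh"].to_numpy(),
            }
        ).reset_index(drop=True)

        # partition sanity: exhaustive, disjoint, and every reverted call opposes
        assert set(calls["category"]).issubset(REVERSAL_CATEGORIES)
        rev = calls["category"] == "reverted"
        assert np.all(
            np.sign(calls.loc[rev, "log2_fc_set1"]) * np.sign(calls.loc[rev, "log2_fc_set2"]) < 0
        )
        self.calls_ = calls
        self.labels_ = category
        self.n_reverted_up_ = int((rev & (calls["aging_direction"] == "up")).sum())
        self.n_reverted_down_ = int((rev & (calls["aging_direction"] == "down")).sum())
        logger.info(
            "reversal calls: %d aging DEGs, %d reverted (%d aging-up, %d aging-down)",
            int(aging.sum()), int(rev.sum()), self.n_reverted_up_, self.n_reverted_down_,
        )
        return self


class DependenceClassifier(BaseEstimator):
    """Partition wild-type treatment DEGs into knockout-dependent/independent.

    ``fit(wt, ko)`` takes the wild-type and knockout treatment ContrastTables
    (treated vs vehicle in each genotype) over one gene universe.
    """

    def __init__(self, fdr_deg: float = 0.2, p_ko: float = 0.05):
        self.fdr_deg = fdr_deg
        self.p_ko = p_ko

    def fit(self, wt: pd.DataFrame, ko: pd.DataFrame):
        DependenceThresholds(self.fdr_deg, self.p_ko)
        t = _aligned({"wt": wt, "ko": ko})
        wt_t, ko_t = t["wt"], t["ko"]
        genes = wt_t.index

        deg = (wt_t["q_bh"] < self.fdr_deg).to_numpy()
        p_ko = ko_t["p_raw"].to_numpy()
        ties = deg & (p_ko == self.p_ko)
        if ties.any():
            logger.info(
                "%d DEG(s) with knockout p exactly at %g resolved to 'dependent'",
                int(ties.sum()), self.p_ko,
            )
        category = np.where(
            ~deg, "not_deg", np.where(p_ko >= self.p_ko, "dependent", "independent")
        ).astype(object)
        wt_lfc = wt_t["log2_fc"].to_numpy()
        wt_direction = np.where(deg, np.where(wt_lfc > 0, "up", "down"), "none").astype(object)

        calls = pd.DataFrame(
            {
                "gene_id": genes,
                "category": category,
                "wt_direction": wt_direction,
                "log2_fc_wt": wt_lfc,
                "p_raw_wt": wt_t["p_raw"].to_numpy(),
                "q_bh_wt": wt_t["q_bh"].to_numpy(),
                "log2_fc_ko": ko_t["log2_fc"].to_numpy(),
                "p_raw_ko": p_ko,
                "q_bh_ko": ko_t["q_bh"].to_numpy(),
            }
        ).reset_index(drop=True)
        assert set(calls["category"]).issubset(DEPENDENCE_CATEGORIES)
        self.calls_ = calls
        self.labels_ = category
        logger.info(
            "dependence calls: %d DEGs -> %d dependent, %d independent",
            int(deg.sum()),
            int((category == "dependent").sum()),
            int((category == "independent").sum()),
        )
        return self


def classify_reversal(
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    set3: pd.DataFrame,
    thresholds: ReversalThresholds | None = None,
) -> pd.DataFrame:
    th = thresholds or ReversalThresholds()
    return ReversalClassifier(th.fdr_set1, th.p_set2, th.p_set3).fit(set1, set2, set3).calls_


def classify_dependence(
    wt: pd.DataFrame, ko: pd.DataFrame, thresholds: DependenceThresholds | None = None
) -> pd.DataFrame:
    th = thresholds or DependenceThresholds()
    return DependenceClassifier(th.fdr_deg, th.p_ko).fit(wt, ko).calls_


def summarize_partition(
    calls: pd.DataFrame,
    denominator_categories: tuple[str, ...] | None = None,
    labels: pd.Series | dict | None = None,
    label_category: str | None = None,
) -> dict:
    """Counts and percentages per category, with the denominator documented.

    ``denominator_categories`` restricts the percentage denominator to a
    subset of categories (e.g. the called-DEG set for the dependence
    partition); by default every category counts.  An optional gene->label
    map tabulates sub-labels within ``label_category`` (e.g. pathway groups
    within the reverted genes), with that category's size as denominator.
    Percentages are rounded to one decimal; an empty denominator yields the
    explicit marker ``None`` rather than a division error.
    """
    if calls.empty:
        raise ValueError("calls table is empty")
    counts = calls["category"].value_counts().to_dict()
    if denominator_categories is None:
        denom = int(len(calls))
    else:
        denom = int(sum(counts.get(c, 0) for c in denominator_categories))
    pct_categories = (
        list(counts) if denominator_categories is None else list(denominator_categories)
    )
    percentages = {
        c: (round(100.0 * counts.get(c, 0) / denom, 1) if denom else None)
        for c in pct_categories
    }
    summary = {
        "counts": {c: int(counts.get(c, 0)) for c in sorted(set(counts) | set(pct_categories))},
        "denominator": denom,
        "percentages": percentages,
    }
    if labels is not None:
        if label_category is None:
            raise ValueError("label_category is required when labels are given")
        lab = pd.Series(labels)
        sub = calls.loc[calls["category"] == label_category, "gene_id"]
        sub_labels = lab.reindex(sub).dropna()
        n_sub = int(len(sub))
        label_counts = sub_labels.value_counts().to_dict()
        summary["label_denominator"] = n_sub
        summary["label_counts"] = {k: int(v) for k, v in label_counts.items()}
        summary["label_percentages"] = {
            k: (round(100.0 * v / n_sub, 1) if n_sub else None)
            for k, v in label_counts.items()
        }
    return summary
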