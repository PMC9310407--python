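import numpy as np
import pandas as pd
import pytest

from rejuvseq import (
    DependenceClassifier,
    DependenceThresholds,
    ReversalClassifier,
    ReversalThresholds,
    classify_dependence,
    classify_reversal,
    summarize_partition,
)

from conftest import make_contrast_table


def reversal_tables(q1, lfc1, p2, lfc2, p3, lfc3=0.1):
    genes = ["g0"]
    s1 = make_contrast_table(genes, [lfc1], [q1], q_bh=[q1])
    s2 = make_contrast_table(genes, [lfc2], [p2])
    s3 = make_contrast_table(genes, [lfc3], [p3])
    return s1, s2, s3


class TestReversalRule:
    @pytest.mark.parametrize(
        "q1, lfc1, p2, lfc2, p3, expected",
        [
            # significant aging-up, opposed and nominally reverted, treated ~ young
            (0.05, 2.0, 0.01, -1.5, 0.4, "reverted"),
            # aging FDR fails: nothing else matters
            (0.5, 2.0, 0.01, -1.5, 0.4, "not_aging_deg"),
            # same-direction treatment shift cannot revert
            (0.05, 2.0, 0.01, 1.0, 0.4, "aging_not_reverted"),
            # treated still differs from young (criterion 3 fails)
            (0.05, 2.0, 0.01, -1.5, 0.01, "aging_not_reverted"),
            # treatment contrast not nominally significant
            (0.05, 2.0, 0.2, -1.5, 0.4, "aging_not_reverted"),
            # aging-down gene reverted upward
            (0.02, -1.0, 0.03, 0.8, 0.9, "reverted"),
            # boundary values fail the strict inequalities
            (0.1, 2.0, 0.01, -1.5, 0.4, "not_aging_deg"),
            (0.05, 2.0, 0.05, -1.5, 0.4, "aging_not_reverted"),
            (0.05, 2.0, 0.01, -1.5, 0.05, "aging_not_reverted"),
        ],
    )
    def test_three_criterion_rule(self, q1, lfc1, p2, lfc2, p3, expected):
        calls = classify_reversal(*reversal_tables(q1, lfc1, p2, lfc2, p3))
        assert calls.loc[0, "category"] == expected
        if expected != "not_aging_deg":
            assert calls.loc[0, "aging_direction"] == ("up" if lfc1 > 0 else "down")

    def test_zero_treatment_fold_change_not_reverted(self):
        calls = classify_reversal(*reversal_tables(0.05, 2.0, 0.01, 0.0, 0.4))
        assert calls.loc[0, "category"] == "aging_not_reverted"

    def test_mismatched_universe_lists_difference(self):
        s1 = make_contrast_table(["a", "b"], [1, 1], [0.5, 0.5])
        s2 = make_contrast_table(["a", "c"], [1, 1], [0.5, 0.5])
        with pytest.raises(ValueError, match="symmetric difference"):
            classify_reversal(s1, s2, s1)

    def test_threshold_monotonicity(self):
        """Relaxing the aging FDR never removes a gene from the aging-DEG set."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(300)]
        tables = [
            make_contrast_table(
                genes, rng.normal(size=300), rng.uniform(size=300)
            )
            for _ in range(3)
        ]
        tight = classify_reversal(*tables, ReversalThresholds(fdr_set1=0.05))
        loose = classify_reversal(*tables, ReversalThresholds(fdr_set1=0.3))
        tight_deg = set(tight.loc[tight["category"] != "not_aging_deg", "gene_id"])
        loose_deg = set(loose.loc[loose["category"] != "not_aging_deg", "gene_id"])
        assert tight_deg <= loose_deg

    def test_partition_exhaustive_and_reversal_signs_oppose(self, reversal_dataset):
        from rejuvseq import ContrastSpec, compute_rpkm, contrast_test

        d = reversal_dataset
        rpkm = compute_rpkm(d["counts"], d["annotation"])
        s1 = contrast_test(rpkm, d["sheet"], ContrastSpec("s1", "young_WT", "old_WT_Veh"))
        s2 = contrast_test(rpkm, d["sheet"], ContrastSpec("s2", "old_WT_Veh", "old_WT_Hes"))
        s3 = contrast_test(rpkm, d["sheet"], ContrastSpec("s3", "young_WT", "old_WT_Hes"))
        calls = classify_reversal(s1, s2, s3)
        assert len(calls) == rpkm.shape[0]
        assert set(calls["category"]) <= {"not_aging_deg", "aging_not_reverted", "reverted"}
        rev = calls[calls["category"] == "reverted"]
        assert (np.sign(rev["log2_fc_set1"]) * np.sign(rev["log2_fc_set2"]) < 0).all()


class TestDependenceRule:
    @pytest.mark.parametrize(
        "q_wt, p_ko, expected",
        [
            (0.1, 0.3, "dependent"),     # response lost in knockout
            (0.1, 0.01, "independent"),  # response retained in knockout
            (0.5, 0.3, "not_deg"),
            (0.1, 0.05, "dependent"),    # tie at the knockout threshold
        ],
    )
    def test_two_contrast_rule(self, q_wt, p_ko, expected):
        wt = make_contrast_table(["g0"], [1.0], [q_wt], q_bh=[q_wt])
        ko = make_contrast_table(["g0"], [0.2], [p_ko])
        calls = classify_dependence(wt, ko)
        assert calls.loc[0, "category"] == expected

    def test_gene_order_equivariance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(100)]
        wt = make_contrast_table(genes, rng.normal(size=100), rng.uniform(size=100))
        ko = make_contrast_table(genes, rng.normal(size=100), rng.uniform(size=100))
        calls = classify_dependence(wt, ko).set_index("gene_id")
        perm = rng.permutation(100)
        calls_perm = classify_dependence(
            wt.iloc[perm].reset_index(drop=True), ko.iloc[perm].reset_index(drop=True)
        ).set_index("gene_id")
        pd.testing.assert_series_equal(
            calls["category"].sort_index(), calls_perm["category"].sort_index()
        )

    def test_deg_partition_disjoint_exhaustive(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        wt = make_contrast_table(genes, rng.normal(size=200), rng.uniform(size=200))
        ko = make_contrast_table(genes, rng.normal(size=200), rng.uniform(size=200))
        calls = classify_dependence(wt, ko, DependenceThresholds(fdr_deg=0.4))
        deg = calls["category"] != "not_deg"
        n_deg = (calls["q_bh_wt"] < 0.4).sum()
        assert deg.sum() == n_deg
        assert (calls.loc[deg, "category"].isin(["dependent", "independent"])).all()


class TestPartitionSummary:
    def test_printed_dependence_partition(self):
        cats = ["dependent"] * 72 + ["independent"] * 19 + ["not_deg"] * 500
        calls = pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(cats))], "category": cats})
        s = summarize_partition(calls, denominator_categories=("dependent", "independent"))
        assert s["denominator"] == 91
        assert s["percentages"]["dependent"] == 79.1
        assert s["percentages"]["independent"] == 20.9
        assert round(s["percentages"]["dependent"]) == 79
        assert round(s["percentages"]["independent"]) == 21

    def test_subgroup_labels_within_category(self):
        calls = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(72)], "category": ["reverted"] * 72}
        )
        labels = pd.Series(
            ["metabolism"] * 53 + ["other"] * 19, index=[f"g{i}" for i in range(72)]
        )
        s = summarize_partition(calls, labels=labels, label_category="reverted")
        assert s["label_percentages"]["metabolism"] == 73.6

    def test_single_category_is_100_percent(self):
        calls = pd.DataFrame({"gene_id": ["a", "b"], "category": ["reverted", "reverted"]})
        assert summarize_partition(calls)["percentages"]["reverted"] == 100.0

    def test_empty_denominator_reports_undefined_marker(self):
        calls = pd.DataFrame({"gene_id": ["a"], "category": ["not_deg"]})
        s = summarize_partition(calls, denominator_categories=("dependent", "independent"))
        assert s["denominator"] == 0
        assert s["percentages"]["dependent"] is None
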