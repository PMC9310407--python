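import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from rejuvseq import (
    ExpressionFilter,
    GeneStandardizer,
    RPKMNormalizer,
    compute_rpkm,
    filter_expressed,
    pca_scores,
    zscore_rows,
)


def frame(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)


def annotation(genes, lengths):
    return pd.DataFrame({"gene_id": genes, "length_bp": lengths})


class TestRPKM:
    def test_direct_formula(self):
        # library of exactly 1e6 reads; 10 reads on a 2 kb gene -> RPKM 5
        counts = frame([[10], [999_990]], genes=["a", "b"])
        ann = annotation(["a", "b"], [2000, 1000])
        rpkm = compute_rpkm(counts, ann)
        assert rpkm.loc["a", "s0"] == pytest.approx(5.0)
        assert rpkm.loc["b", "s0"] == pytest.approx(999_990.0)  # 1 kb gene: RPKM = count

    def test_zero_count_gives_zero(self):
        counts = frame([[0], [100]])
        rpkm = compute_rpkm(counts, annotation(["g0", "g1"], [500, 500]))
        assert rpkm.loc["g0", "s0"] == 0.0

    def test_depth_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = frame(rng.integers(0, 500, size=(30, 4)))
        ann = annotation(counts.index, rng.integers(200, 5000, size=30))
        doubled = counts.copy()
        doubled["s2"] = counts["s2"] * 2
        pd.testing.assert_frame_equal(compute_rpkm(counts, ann), compute_rpkm(doubled, ann))

    def test_missing_annotation_lists_genes(self):
        counts = frame([[1], [2]], genes=["known", "orphan"])
        with pytest.raises(ValueError, match="orphan"):
            compute_rpkm(counts, annotation(["known"], [100]))

    def test_zero_library_names_sample(self):
        counts = frame([[5, 0], [5, 0]], samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            compute_rpkm(counts, annotation(["g0", "g1"], [100, 100]))


class TestFilter:
    def test_half_of_samples_passing_is_kept(self):
        rpkm = frame([[5, 5, 0, 0]])
        assert list(filter_expressed(rpkm)) == ["g0"]

    def test_threshold_is_strict(self):
        rpkm = frame([[4, 4, 4, 4]])
        assert list(filter_expressed(rpkm)) == []

    def test_matches_bruteforce_rule(self):
        rng = np.random.default_rng(1)
        rpkm = frame(rng.gamma(2.0, 4.0, size=(1000, 12)))
        retained = set(filter_expressed(rpkm, threshold=4.0, min_fraction=0.5))
        expected = set()
        for gene in rpkm.index:  # independent double-loop re-evaluation
            n_pass = sum(1 for v in rpkm.loc[gene] if v > 4.0)
            if n_pass / rpkm.shape[1] >= 0.5:
                expected.add(gene)
        assert retained == expected

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        rpkm = frame(rng.gamma(2.0, 4.0, size=(200, 8)))
        once = filter_expressed(rpkm)
        twice = filter_expressed(rpkm.loc[once])
        assert list(once) == list(twice)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ExpressionFilter().fit(np.empty((4, 0)))

    def test_sklearn_selector_api(self):
        rpkm = frame([[5, 5, 5, 5], [0, 0, 0, 0]])
        sel = ExpressionFilter().fit(rpkm.T)
        assert list(sel.get_support()) == [True, False]
        assert clone(sel).get_params() == sel.get_params()


class TestZScore:
    def test_row_mean_zero_sd_one(self):
        z = zscore_rows(frame([[1, 2, 3]]))
        row = z.loc["g0"]
        assert row.mean() == pytest.approx(0.0, abs=1e-12)
        assert row.std(ddof=1) == pytest.approx(1.0)

    def test_constant_row_maps_to_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="rejuvseq.expression"):
            z = zscore_rows(frame([[7, 7, 7]]))
        assert (z.loc["g0"] == 0).all()
        assert any("constant" in rec.message for rec in caplog.records)

    def test_matches_definition_on_random_matrix(self):
        rng = np.random.default_rng(3)
        expr = frame(rng.normal(10, 3, size=(50, 6)))
        z = zscore_rows(expr)
        for gene in expr.index[:10]:
            x = expr.loc[gene].to_numpy()
            expected = (x - x.mean()) / x.std(ddof=1)
            np.testing.assert_allclose(z.loc[gene].to_numpy(), expected, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            GeneStandardizer().fit(np.array([[1.0, 2.0]]))


class TestPCA:
    def test_rank_one_matrix_first_component_dominates(self):
        u = np.arange(1, 6, dtype=float)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        z = frame(np.outer(u, v))
        _, _, evr = pca_scores(z, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthogonal_and_evr_sorted(self):
        rng = np.random.default_rng(4)
        z = frame(rng.normal(size=(40, 8)))
        _, loadings, evr = pca_scores(z, 4)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12

    def test_scores_match_eigendecomposition(self):
        z = frame([[2.0, 0.0, 1.0], [1.0, 3.0, -1.0], [0.5, 0.5, 4.0]])
        scores, _, evr = pca_scores(z, 2)
        x = z.T.to_numpy()
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        expected = xc @ evecs[:, order[:2]]
        # eigenvector sign is arbitrary; compare up to per-component sign
        for j in range(2):
            assert np.allclose(scores.iloc[:, j], expected[:, j], atol=1e-9) or np.allclose(
                scores.iloc[:, j], -expected[:, j], atol=1e-9
            )
        np.testing.assert_allclose(evr, (evals[order] / evals.sum())[:2], atol=1e-12)

    def test_component_bounds_checked(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_scores(frame(np.eye(3)), 5)
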