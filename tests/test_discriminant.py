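"""Canonical LDA (tolerance, eigenchain, structure, classification) and PCA."""

import numpy as np
import pandas as pd
import pytest

import honeyvola as hv
from honeyvola.screening import scatter_matrices
from tests.conftest import make_sample_table


class TestToleranceScreen:
    def test_duplicated_column_excluded_with_zero_tolerance(self, three_group_table):
        df = three_group_table.df.copy()
        df["copy"] = df["v0"]
        kept, excluded = hv.tolerance_screen(hv.SampleTable(df))
        assert len(excluded) == 1
        (name, tol), = excluded.items()
        assert name in ("v0", "copy")
        assert tol == pytest.approx(0.0, abs=1e-10)
        assert len(kept) == len(three_group_table.compounds)

    def test_orthogonal_variables_all_kept_with_high_tolerance(self, rng):
        # construct exactly orthogonal within-group columns
        q, _ = np.linalg.qr(rng.normal(size=(30, 4)))
        df = pd.DataFrame(np.abs(q) + 1.0, columns=[f"v{j}" for j in range(4)])
        df.insert(0, "group", ["A"] * 15 + ["B"] * 15)
        df.index = [f"s{i}" for i in range(30)]
        df.index.name = "sample_id"
        kept, excluded = hv.tolerance_screen(hv.SampleTable(df))
        assert excluded == {}
        assert len(kept) == 4

    def test_matches_inverse_correlation_oracle(self, rng):
        # tolerance_j = 1 / (R^-1)_jj on the pooled within-group correlation
        t = make_sample_table(rng, {"A": 20, "B": 20}, p=5)
        from honeyvola.discriminant import _pooled_within_centered, _tolerances

        xw = _pooled_within_centered(t, t.compounds)
        corr = np.corrcoef(xw, rowvar=False)
        oracle = 1.0 / np.diag(np.linalg.inv(corr))
        np.testing.assert_allclose(_tolerances(xw), oracle, atol=1e-10)

    def test_all_excluded_is_an_error(self, rng):
        t = make_sample_table(rng, {"A": 5, "B": 5}, p=1)
        df = t.df.copy()
        df["v0"] = df.groupby("group")["v0"].transform("mean")  # zero within-variance
        with pytest.raises(ValueError, match="excluded every variable"):
            hv.tolerance_screen(hv.SampleTable(df))


class TestFitLda:
    def test_two_groups_give_one_function_with_anova_identity(self, rng):
        t = make_sample_table(rng, {"A": 12, "B": 10}, p=3, means=[0.0, 2.0])
        model = hv.fit_lda(t)
        assert model.n_functions == 1
        scores = model.transform(t)["F1"]
        grand = scores.mean()
        ssb = sum(
            (scores[t.df["group"] == g].mean() - grand) ** 2 * (t.df["group"] == g).sum()
            for g in ("A", "B")
        )
        sst = ((scores - grand) ** 2).sum()
        assert model.canonical_corr[0] ** 2 == pytest.approx(ssb / sst, rel=1e-9)

    def test_five_groups_31_variables_form_four_functions(self, rng):
        sizes = {"Egypt": 7, "Morocco": 6, "Greece": 17, "Spain": 8, "Nectar": 6}
        t = make_sample_table(rng, sizes, p=31, means=[0, 1, 2, 3, 4])
        model = hv.fit_lda(t)
        assert model.n_functions == 4
        assert model.pct_variance.sum() == pytest.approx(100.0)

    def test_eigenvalues_match_dense_generalized_eigenproblem(self, three_group_table):
        model = hv.fit_lda(three_group_table, screen=False)
        w, b = scatter_matrices(three_group_table)
        oracle = np.sort(np.linalg.eigvals(np.linalg.solve(w, b)).real)[::-1]
        np.testing.assert_allclose(model.eigenvalues, oracle[: model.n_functions], atol=1e-8)

    def test_bartlett_lambda_identity(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        lam1 = model.wilks_chain[0][0]
        assert lam1 == pytest.approx(np.prod(1 / (1 + model.eigenvalues)), abs=1e-10)

    def test_eigenvalues_descending_and_canonical_corr_bounded(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        assert ((model.canonical_corr >= 0) & (model.canonical_corr < 1)).all()

    def test_scores_have_unit_pooled_within_variance(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        scores = model.transform(three_group_table).to_numpy()
        gl = three_group_table.df["group"].to_numpy()
        sw = scores.copy()
        for g in set(gl):
            sw[gl == g] -= sw[gl == g].mean(axis=0)
        n_minus_g = len(gl) - len(set(gl))
        np.testing.assert_allclose((sw**2).sum(axis=0) / n_minus_g, 1.0, rtol=1e-8)

    def test_scores_invariant_under_variable_rescaling(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        df = three_group_table.df.copy()
        df["v1"] = df["v1"] * 40.0 + 3.0
        model2 = hv.fit_lda(hv.SampleTable(df))
        s1 = model.transform(three_group_table).to_numpy()
        s2 = model2.transform(hv.SampleTable(df)).to_numpy()
        for k in range(s1.shape[1]):
            assert np.allclose(s1[:, k], s2[:, k], atol=1e-6) or np.allclose(
                s1[:, k], -s2[:, k], atol=1e-6
            )

    def test_singular_scatter_names_variables(self, rng):
        t = make_sample_table(rng, {"A": 3, "B": 3}, p=8)
        with pytest.raises(ValueError, match="singular|excluded"):
            hv.fit_lda(t, screen=False)


class TestStructureAndPower:
    def test_structure_matches_direct_pooled_correlation(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        scores = model.transform(three_group_table).to_numpy()
        x = three_group_table.conc[model.compounds].to_numpy()
        gl = three_group_table.df["group"].to_numpy()
        xw, sw = x.copy(), scores.copy()
        for g in set(gl):
            xw[gl == g] -= xw[gl == g].mean(axis=0)
            sw[gl == g] -= sw[gl == g].mean(axis=0)
        for j in range(x.shape[1]):
            for k in range(scores.shape[1]):
                oracle = (xw[:, j] @ sw[:, k]) / np.sqrt(
                    (xw[:, j] ** 2).sum() * (sw[:, k] ** 2).sum()
                )
                assert model.structure.iloc[j, k] == pytest.approx(oracle, abs=1e-10)

    def test_structure_entries_bounded(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        assert (model.structure.abs().to_numpy() <= 1 + 1e-12).all()

    def test_variable_equal_to_score_has_power_one(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        df = three_group_table.df.copy()
        scores = model.transform(three_group_table)
        df["probe"] = scores["F1"] - scores["F1"].min()  # nonneg copy of the score
        model2 = hv.fit_lda(hv.SampleTable(df))
        ranking = dict(hv.discrimination_power(model2))
        assert ranking["probe"] == pytest.approx(1.0, abs=1e-6)

    def test_ranking_sorted_descending_with_stable_ties(self, three_group_table):
        ranking = hv.discrimination_power(hv.fit_lda(three_group_table))
        powers = [p for _, p in ranking]
        assert powers == sorted(powers, reverse=True)


class TestClassify:
    def test_separated_clouds_classified_perfectly(self, rng):
        t = make_sample_table(rng, {"A": 10, "B": 10}, p=2, means=[0.0, 50.0])
        model = hv.fit_lda(t)
        cm = hv.classify(model, t, method="original")
        assert cm.overall_rate == 100.0

    def test_confusion_matches_exhaustive_distance_oracle(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        cm = hv.classify(model, three_group_table, method="original")
        scores = model.transform(three_group_table).to_numpy()
        cent = model.centroids.to_numpy()
        oracle = pd.DataFrame(0, index=model.group_labels, columns=model.group_labels)
        for i, true in enumerate(three_group_table.df["group"]):
            d = ((scores[i] - cent) ** 2).sum(axis=1)
            oracle.loc[true, model.group_labels[int(np.argmin(d))]] += 1
        pd.testing.assert_frame_equal(cm.counts, oracle)

    def test_matches_sklearn_predictions(self, three_group_table):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        model = hv.fit_lda(three_group_table)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        x = three_group_table.conc.to_numpy()
        y = three_group_table.df["group"].to_numpy()
        sk.fit(x, y)
        assert model.predict(three_group_table) == list(sk.predict(x))

    def test_row_sums_equal_group_sizes_both_methods(self, three_group_table):
        model = hv.fit_lda(three_group_table)
        sizes = three_group_table.df["group"].value_counts()
        for method in ("original", "loocv"):
            cm = hv.classify(model, three_group_table, method=method)
            for g in model.group_labels:
                assert cm.counts.loc[g].sum() == sizes[g]
            assert cm.overall_rate == pytest.approx(
                100 * np.trace(cm.counts) / len(three_group_table)
            )

    def test_loocv_equals_original_on_duplicated_points(self, rng):
        base = rng.normal(size=(3, 2)) * 5
        rows, labels = [], []
        for gi, g in enumerate("ABC"):
            for _ in range(6):
                rows.append(np.abs(base[gi]) + 1.0)
                labels.append(g)
        df = pd.DataFrame(rows, columns=["v0", "v1"])
        df.insert(0, "group", labels)
        df.index = [f"s{i}" for i in range(len(df))]
        df.index.name = "sample_id"
        # jitter one coordinate so scatter is nonsingular, duplicates remain tight
        jitter = rng.normal(scale=1e-3, size=len(df))
        df["v0"] = df["v0"] + np.abs(jitter)
        t = hv.SampleTable(df)
        model = hv.fit_lda(t)
        cm_orig = hv.classify(model, t, method="original")
        cm_loo = hv.classify(model, t, method="loocv")
        pd.testing.assert_frame_equal(cm_orig.counts, cm_loo.counts)

    def test_proportional_priors_shift_boundary(self, rng):
        t = make_sample_table(rng, {"A": 30, "B": 5}, p=2, means=[0.0, 1.0])
        eq = hv.fit_lda(t, priors="equal")
        prop = hv.fit_lda(t, priors="proportional")
        assert eq.priors["A"] == pytest.approx(0.5)
        assert prop.priors["A"] == pytest.approx(30 / 35)


class TestPca:
    def test_two_perfectly_correlated_variables(self, rng):
        v = np.abs(rng.normal(size=20)) + 1
        df = pd.DataFrame({"group": "A", "x": v, "y": 2 * v + 1})
        df.index = [f"s{i}" for i in range(20)]
        df.index.name = "sample_id"
        res = hv.fit_pca(hv.SampleTable(df))
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert res.pct_variance[0] == pytest.approx(100.0)
        assert res.retained == 1

    def test_eigenvalue_sum_equals_variable_count(self, three_group_table):
        res = hv.fit_pca(three_group_table)
        assert res.eigenvalues.sum() == pytest.approx(len(three_group_table.compounds))

    def test_matches_explicit_correlation_eigendecomposition(self, three_group_table):
        res = hv.fit_pca(three_group_table)
        corr = np.corrcoef(three_group_table.conc.to_numpy(), rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-10)

    def test_cumulative_percentages_monotone_to_100(self, three_group_table):
        res = hv.fit_pca(three_group_table)
        assert (np.diff(res.cumulative_pct) >= -1e-12).all()
        assert res.cumulative_pct[-1] == pytest.approx(100.0, abs=1e-8)

    def test_loadings_orientation_deterministic(self, three_group_table):
        res = hv.fit_pca(three_group_table)
        for k in range(len(res.eigenvalues)):
            col = res.loadings.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] >= 0

    def test_constant_variable_dropped_with_warning(self, three_group_table, caplog):
        df = three_group_table.df.copy()
        df["flat"] = 3.0
        with caplog.at_level("WARNING"):
            res = hv.fit_pca(hv.SampleTable(df))
        assert res.dropped == ["flat"]

    def test_scores_centered(self, three_group_table):
        res = hv.fit_pca(three_group_table)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
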