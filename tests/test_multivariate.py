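"""PCA/OPLS-DA core against SVD and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbstscreen.multivariate import (preprocess, PCA, flag_outliers, OPLSDA,
                                     cv_anova, rank_biomarkers)


def frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i:03d}" for i in
                                    range(arr.shape[0])],
                        columns=[f"g{j}" for j in range(arr.shape[1])])


def centered_frame(rng, n, k):
    X = rng.normal(size=(n, k))
    return frame(X - X.mean(0))


class TestPreprocess:
    def test_log_pareto_hand_example(self):
        vals = frame([[1.0, 2.0], [10.0, 2.5], [100.0, 3.0]])
        prep = preprocess(vals)
        # log10 of column 0 is (0,1,2): mean 1, sd 1 -> scaled (-1,0,1)
        assert np.allclose(prep.X["g0"], [-1.0, 0.0, 1.0])

    def test_zero_variance_column_dropped(self):
        vals = frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        prep = preprocess(vals)
        assert prep.dropped == ("g1",)
        assert list(prep.X.columns) == ["g0"]

    def test_inverse_round_trip(self, rng):
        vals = frame(10 ** rng.normal(size=(8, 4)))
        prep = preprocess(vals)
        back = prep.inverse_transform(prep.X)
        assert np.allclose(back, vals[back.columns], rtol=1e-10)

    def test_nonpositive_values_named_in_error(self):
        vals = frame([[1.0, 2.0], [0.0, 3.0], [2.0, 4.0]])
        with pytest.raises(ValueError, match="s001"):
            preprocess(vals)

    def test_columns_centered(self, rng):
        vals = frame(10 ** rng.normal(size=(20, 5)))
        prep = preprocess(vals)
        assert np.abs(prep.X.mean(0)).max() < 1e-10


class TestNipalsPca:
    def test_rank_one_matrix_fully_explained(self):
        X = frame(np.outer([1, 2, 3, 4.0], [1, 0, -1.0]))
        X = X - X.mean(0)
        res = PCA(X, 1).fit()
        assert res.r2x[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self, rng):
        X = centered_frame(rng, 10, 5)
        res = PCA(X, 3).fit()
        U, S, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        for a in range(3):
            t = res.scores.iloc[:, a].to_numpy()
            sv = U[:, a] * S[a]
            assert min(np.abs(t - sv).max(), np.abs(t + sv).max()) < 1e-6
            assert res.r2x[a] == pytest.approx(S[a] ** 2 / (S ** 2).sum(),
                                               abs=1e-9)

    def test_r2x_non_increasing_and_bounded(self, rng):
        X = centered_frame(rng, 30, 8)
        res = PCA(X, 5).fit()
        assert np.all(np.diff(res.r2x) <= 1e-12)
        assert res.r2x.sum() <= 1 + 1e-12

    def test_loadings_orthonormal_scores_orthogonal(self, rng):
        X = centered_frame(rng, 20, 6)
        res = PCA(X, 4).fit()
        P = res.loadings.to_numpy()
        assert np.allclose(P.T @ P, np.eye(4), atol=1e-8)
        T = res.scores.to_numpy()
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-6


class TestHotelling:
    def test_origin_sample_has_zero_t2(self, rng):
        X = centered_frame(rng, 20, 5)
        X.iloc[0] = 0.0
        X = X - X.mean(0)
        res = PCA(X, 2).fit()
        t2, limit = res.hotelling_t2()
        # the sample nearest the score origin has the smallest T2
        d = (res.scores ** 2).sum(axis=1)
        assert t2.idxmin() == d.idxmin()
        assert limit > 0

    def test_single_component_closed_form(self, rng):
        X = centered_frame(rng, 25, 4)
        res = PCA(X, 1).fit()
        _, limit = res.hotelling_t2(alpha=0.05)
        N = 25
        expected = ((N ** 2 - 1) / (N * (N - 1))) * stats.f.ppf(0.95, 1, N - 1)
        assert limit == pytest.approx(expected, rel=1e-12)

    def test_exceedance_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        X = centered_frame(rng, 2000, 5)
        res = PCA(X, 2).fit()
        t2, limit = res.hotelling_t2(alpha=0.05)
        rate = (t2 > limit).mean()
        assert 0.035 <= rate <= 0.065

    def test_too_few_samples_raise(self, rng):
        X = centered_frame(rng, 3, 5)
        res = PCA(X, 3).fit()
        with pytest.raises(ValueError):
            res.hotelling_t2()


class TestDmodx:
    def test_in_plane_sample_has_smallest_distance(self, rng):
        X = centered_frame(rng, 30, 6)
        res = PCA(X, 2).fit()
        T, P = res.scores.to_numpy(), res.loadings.to_numpy()
        # replace sample 0 with its own projection: residual exactly 0
        X2 = X.copy()
        X2.iloc[0] = T[0] @ P.T
        res2 = PCA(X2 - X2.mean(0), 2).fit()
        dm, crit = res2.dmodx()
        assert dm.iloc[0] < dm.iloc[1:].min()

    def test_normalized_mean_near_one(self, rng):
        X = centered_frame(rng, 100, 8)
        res = PCA(X, 2).fit()
        dm, _ = res.dmodx()
        assert 0.8 <= dm.mean() <= 1.1

    def test_large_injected_residual_exceeds_limit(self, rng):
        # strong two-factor structure + small noise, so a residual spike
        # cannot be absorbed into the fitted plane
        T = rng.normal(size=(50, 2)) * [5.0, 3.0]
        P = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        X = frame(T @ P.T + 0.1 * rng.normal(size=(50, 6)))
        X = X - X.mean(0)
        res = PCA(X, 2).fit()
        E = X.to_numpy() - res.scores.to_numpy() @ res.loadings.to_numpy().T
        pooled = np.sqrt((E ** 2).sum() / ((50 - 2 - 1) * (6 - 2)))
        spike = np.linalg.qr(np.c_[P, rng.normal(size=6)])[0][:, 2]
        X.iloc[0] += 10 * pooled * spike * np.sqrt(6 - 2)
        res2 = PCA(X - X.mean(0), 2).fit()
        dm, crit = res2.dmodx()
        assert dm.iloc[0] > crit


class TestOutlierFlagging:
    def test_clean_data_flags_modestly(self):
        rng = np.random.default_rng(7)
        X = centered_frame(rng, 200, 6)
        rep = flag_outliers(PCA(X, 2).fit())
        assert 0.0 <= len(rep.excluded) / 200 <= 0.15

    def test_gross_outlier_flagged(self, rng):
        X = centered_frame(rng, 40, 5)
        X.iloc[3] = 10.0
        X = X - X.mean(0)
        rep = flag_outliers(PCA(X, 2).fit())
        assert "s003" in rep.excluded

    def test_small_clean_fixture_may_flag_nothing(self):
        rng = np.random.default_rng(11)
        X = frame(rng.normal(0, 1, size=(10, 4)) * 0.1
                  + np.linspace(-1, 1, 10)[:, None])
        X = X - X.mean(0)
        rep = flag_outliers(PCA(X, 2).fit())
        assert isinstance(rep.excluded, tuple)  # empty exclusion is valid


def two_class_frame(rng, n=60, k=5, effect=2.0, nuisance=0.0):
    y = pd.Series(np.r_[np.zeros(n // 2), np.ones(n // 2)],
                  index=[f"s{i:03d}" for i in range(n)])
    X = rng.normal(size=(n, k))
    X[:, 0] += effect * (y.to_numpy() - 0.5)
    if nuisance:
        X[:, 1] += nuisance * rng.normal(size=n)
    X = X - X.mean(0)
    return frame(X), y


class TestOplsDa:
    def test_orthogonal_component_captures_nuisance(self, rng):
        """A constructed class-unrelated high-variance direction loads on
        the orthogonal component; removing it sharpens the predictive
        score's class correlation."""
        X, y = two_class_frame(rng, n=80, effect=1.5, nuisance=6.0)
        res = OPLSDA(X, y, n_orth=1).fit()
        w_o = res._fit["W_o"][0]
        assert np.abs(w_o[1]) > 0.9          # nuisance direction g1
        plain = np.corrcoef(X.to_numpy()[:, 0] * 0 + PCA(X, 1).fit()
                            .scores.iloc[:, 0], y)[0, 1]
        sharp = np.corrcoef(res.scores, y)[0, 1]
        assert abs(sharp) > abs(plain)

    def test_predictive_score_orthogonal_to_orthogonal_scores(self, rng):
        X, y = two_class_frame(rng, nuisance=4.0)
        res = OPLSDA(X, y, n_orth=2).fit()
        t = res.scores.to_numpy()
        for c in res.orthogonal_scores.columns:
            assert abs(t @ res.orthogonal_scores[c].to_numpy()) < 1e-6 * (
                np.linalg.norm(t) * np.linalg.norm(res.orthogonal_scores[c]))

    def test_treated_class_mean_score_positive(self, rng):
        X, y = two_class_frame(rng)
        res = OPLSDA(X, y).fit()
        assert res.scores[y == 1].mean() > res.scores[y == 0].mean()

    def test_zero_class_covariance_flagged_uninformative(self):
        # columns constructed exactly orthogonal to the centered class vector
        x = np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])
        X = frame(np.column_stack([x, 2 * x]))
        y = pd.Series([0, 0, 0, 1, 1, 1.0], index=X.index)
        res = OPLSDA(X, y, n_orth=0, folds=2).fit()
        assert res.uninformative

    def test_separable_classes_give_high_q2(self, rng):
        X, y = two_class_frame(rng, effect=8.0)
        res = OPLSDA(X, y).fit()
        assert res.q2 > 0.9

    def test_q2_never_exceeds_r2y(self, rng):
        for seed in range(5):
            X, y = two_class_frame(np.random.default_rng(seed), effect=1.0)
            res = OPLSDA(X, y).fit()
            assert res.q2 <= res.r2y + 1e-9

    def test_single_class_and_bad_folds_rejected(self, rng):
        X, y = two_class_frame(rng)
        with pytest.raises(ValueError):
            OPLSDA(X, pd.Series(1.0, index=X.index))
        with pytest.raises(ValueError):
            OPLSDA(X, y, folds=1)

    def test_permuted_labels_destroy_q2(self, rng):
        X, y = two_class_frame(rng, effect=1.5)
        low = 0
        for i in range(30):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            low += OPLSDA(X, yp).fit().q2 <= 0.05
        assert low >= 27


class TestCvAnova:
    def test_perfect_separation_highly_significant(self, rng):
        X, y = two_class_frame(rng, effect=10.0)
        res = OPLSDA(X, y).fit()
        assert res.cv_anova.p < 1e-6

    def test_press_exceeding_ss_truncates(self):
        y = np.array([0.0, 0, 1, 1])
        res = cv_anova(y, press=10.0, n_components=1)
        assert res.F == 0.0 and res.p == 1.0


class TestSPlot:
    def test_gene_equal_to_score_has_unit_correlation(self, rng):
        X, y = two_class_frame(rng, effect=3.0)
        res = OPLSDA(X, y, n_orth=0).fit()
        X2 = X.copy()
        X2["gt"] = res.scores
        res2 = OPLSDA(X2 - X2.mean(0), y, n_orth=0).fit()
        sp = res2.s_plot().set_index("gene")
        assert sp.loc["gt", "pcorr1"] == pytest.approx(1.0, abs=0.01)

    def test_sign_consistency_p1_vs_pcorr1(self, rng):
        X, y = two_class_frame(rng)
        sp = OPLSDA(X, y).fit().s_plot()
        nz = sp[(sp.p1.abs() > 1e-12) & sp.defined]
        assert (np.sign(nz.p1) == np.sign(nz.pcorr1)).all()

    def test_independent_gene_has_small_correlation(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X, y = two_class_frame(rng, n=200, effect=2.0)
            sp = OPLSDA(X, y, n_orth=0).fit().s_plot().set_index("gene")
            hits += abs(sp.loc["g4", "pcorr1"]) < 0.2
        assert hits >= 36  # >= ~95% (g4 is independent of class)


class TestRanking:
    def test_null_splot_gives_empty_panel(self):
        sp = pd.DataFrame({"gene": ["a", "b"], "p1": [0.0, 0.0],
                           "pcorr1": [0.0, 0.0], "defined": [True, True]})
        ranked = rank_biomarkers(sp)
        assert not ranked.in_panel.any()

    def test_zero_threshold_keeps_everything_ordered(self):
        sp = pd.DataFrame({"gene": list("abc"), "p1": [0.1, 0.3, 0.2],
                           "pcorr1": [0.2, 0.9, -0.5],
                           "defined": [True, True, True]})
        ranked = rank_biomarkers(sp, pcorr_threshold=0.0)
        assert list(ranked.gene) == ["b", "c", "a"]
        assert ranked.in_panel.sum() == 3
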