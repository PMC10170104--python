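import numpy as np
import pytest

from metabextract.pcdfa import (cohens_kappa, fit_pcdfa, mccv,
                                select_features_anova)
from metabextract.synthetic_data import (EffectSpec, SimulationConfig, simulate)


def two_clusters(rng, n_per=10, p=8, sep=10.0, noise=0.1):
    a = rng.normal(0.0, noise, (n_per, p))
    b = rng.normal(sep, noise, (n_per, p))
    X = np.vstack([a, b])
    labels = ["a"] * n_per + ["b"] * n_per
    return X, labels


class TestFeatureSelection:
    def test_null_table_selects_at_most_alpha_fraction(self):
        cfg = SimulationConfig(n_features=400, replicates={"I": 5, "III": 5},
                               n_qc=2, base_cv=0.1, lipophilic_fraction=0.0,
                               seed=21)
        table, _ = simulate(cfg)
        selected = select_features_anova(table, alpha=0.05)
        assert len(selected) / 400 <= 0.05

    def test_strong_effects_are_selected(self):
        cfg = SimulationConfig(
            n_features=300, replicates={"I": 5, "III": 5}, n_qc=2,
            base_cv=0.1, lipophilic_fraction=0.0,
            extra_class_fractions={"up": 100 / 300},
            effects=[EffectSpec(target="up", groups=("III",), fold_change=4.0)],
            seed=22)
        table, truth = simulate(cfg)
        selected = set(select_features_anova(table, alpha=0.05))
        true_up = set(truth.feature_info.index[
            truth.feature_info["feature_class"] == "up"])
        assert len(selected & true_up) >= 95

    def test_alpha_zero_selects_nothing(self):
        cfg = SimulationConfig(n_features=50, replicates={"I": 3, "III": 3},
                               n_qc=2, base_cv=0.1, lipophilic_fraction=0.0, seed=23)
        table, _ = simulate(cfg)
        assert select_features_anova(table, alpha=0.0) == []


class TestFitPCDFA:
    def test_separable_clusters_split_on_df1(self, rng):
        X, labels = two_clusters(rng)
        model = fit_pcdfa(X, labels)
        df1 = model.df_scores[:, 0]
        la = np.asarray(labels) == "a"
        gap = abs(df1[la].mean() - df1[~la].mean())
        spread = max(np.ptp(df1[la]), np.ptp(df1[~la]))
        assert gap > spread  # zero overlap between classes

    def test_kaiser_floor_forces_two_components(self, rng):
        # all variance on one coordinate: Kaiser alone would retain 1
        n = 12
        X = np.zeros((n, 5))
        X[:, 0] = rng.normal(0, 5, n)
        labels = ["a"] * 6 + ["b"] * 6
        model = fit_pcdfa(X, labels)
        assert model.n_components == 2

    def test_pca_identities(self, rng):
        X = rng.normal(0, 1, (15, 6))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        model = fit_pcdfa(X, labels)
        Xc = X - model.mean_
        scores = Xc @ model.loadings
        assert np.abs(scores.mean(axis=0)).max() < 1e-8
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert scores.var(axis=0, ddof=1).sum() == pytest.approx(
            Xc.var(axis=0, ddof=1).sum(), rel=1e-10)

    def test_df1_maximizes_scatter_ratio(self, rng):
        # any random direction in retained-PC space has a lower between/within ratio
        n_per = 8
        X = np.vstack([rng.normal(0, 1, (n_per, 4)),
                       rng.normal(2, 1, (n_per, 4)),
                       rng.normal(-2, 1.5, (n_per, 4))])
        labels = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
        model = fit_pcdfa(X, labels)
        k = model.n_components
        Xc = X - model.mean_
        scores = (Xc @ model.loadings)[:, :k]
        labels_arr = np.asarray(labels)

        def ratio(w):
            proj = scores @ w
            overall = proj.mean()
            sb = sw = 0.0
            for c in set(labels):
                sub = proj[labels_arr == c]
                sb += len(sub) * (sub.mean() - overall) ** 2
                sw += ((sub - sub.mean()) ** 2).sum()
            return sb / sw

        best = ratio(model.df_axes[:, 0])
        for _ in range(200):
            w = rng.normal(size=k)
            w /= np.linalg.norm(w)
            assert ratio(w) <= best + 1e-9

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="class"):
            fit_pcdfa(rng.normal(0, 1, (3, 4)), ["a", "a", "b"])
        with pytest.raises(ValueError, match="features"):
            fit_pcdfa(rng.normal(0, 1, (6, 1)), ["a"] * 3 + ["b"] * 3)


class TestCohensKappa:
    def test_diagonal_is_one(self):
        assert cohens_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        assert cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # p_o = 0.9, p_e = 0.5 -> kappa = 0.8; accuracy = trace/total = 0.9
        conf = np.array([[45, 5], [5, 45]])
        assert cohens_kappa(conf) == pytest.approx(0.8)
        assert np.trace(conf) / conf.sum() == pytest.approx(0.9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.ones((2, 3)))

    def test_degenerate_single_class(self):
        assert cohens_kappa([[10]]) == 1.0


class TestMCCV:
    def test_separable_classes_perfect_prediction(self, rng):
        X, labels = two_clusters(rng, n_per=10)
        res = mccv(X, labels, n_iter=50, test_fraction=0.3, seed=1)
        assert res.mean_accuracy == 1.0
        assert res.kappa == 1.0

    def test_permuted_labels_kappa_near_zero(self, rng):
        X = rng.normal(0, 1, (30, 12))
        labels = np.repeat([f"g{i}" for i in range(6)], 5)
        labels = rng.permutation(labels)
        res = mccv(X, labels, n_iter=100, test_fraction=0.3, seed=2)
        assert abs(res.kappa) <= 0.1

    def test_reproducible_for_fixed_seed(self, rng):
        X, labels = two_clusters(rng, n_per=6, noise=3.0)
        r1 = mccv(X, labels, n_iter=20, seed=5)
        r2 = mccv(X, labels, n_iter=20, seed=5)
        assert np.array_equal(r1.accuracies, r2.accuracies)
        assert r1.confusion.equals(r2.confusion)

    def test_accuracy_matches_confusion_trace(self, rng):
        X, labels = two_clusters(rng, n_per=6, sep=1.0, noise=1.0)
        res = mccv(X, labels, n_iter=40, seed=3)
        conf = res.confusion.to_numpy()
        assert np.trace(conf) / conf.sum() == pytest.approx(
            res.accuracies.mean(), abs=1e-12)

    def test_scaling_invariance(self, rng):
        X, labels = two_clusters(rng, n_per=6, sep=1.5, noise=1.0)
        r1 = mccv(X, labels, n_iter=30, seed=4)
        r2 = mccv(X * 7.3, labels, n_iter=30, seed=4)
        assert r1.mean_accuracy == pytest.approx(r2.mean_accuracy)
        assert r1.kappa == pytest.approx(r2.kappa)

    def test_infeasible_test_fraction_rejected(self, rng):
        X, labels = two_clusters(rng, n_per=3)
        with pytest.raises(ValueError, match="training"):
            mccv(X, labels, n_iter=5, test_fraction=0.5)

    def test_variance_shrinks_on_separable_data(self, rng):
        X, labels = two_clusters(rng, n_per=10)
        res = mccv(X, labels, n_iter=100, seed=6)
        assert res.accuracies.var() == pytest.approx(0.0, abs=1e-12)


class TestTrainTestHygiene:
    def test_test_fold_outlier_does_not_change_model_or_other_predictions(self, rng):
        X, labels = two_clusters(rng, n_per=8, sep=2.0, noise=1.0)
        labels = np.asarray(labels)
        test_idx = np.array([0, 1, 8, 9])
        train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)

        model_a = fit_pcdfa(X[train_idx], labels[train_idx])
        pred_a = model_a.classify(X[test_idx])

        X_poisoned = X.copy()
        X_poisoned[test_idx[0]] += 1e6  # outlier confined to the test fold
        model_b = fit_pcdfa(X_poisoned[train_idx], labels[train_idx])
        pred_b = model_b.classify(X_poisoned[test_idx])

        assert np.array_equal(model_a.mean_, model_b.mean_)
        assert np.array_equal(model_a.loadings, model_b.loadings)
        assert np.array_equal(model_a.df_axes, model_b.df_axes)
        assert model_a.n_components == model_b.n_components
        # predictions for the untouched test samples are identical
        assert np.array_equal(pred_a[1:], pred_b[1:])
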