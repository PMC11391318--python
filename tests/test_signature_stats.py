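"""PCA, discriminant classification, pDFA, kappa, H_s, binomial tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vocalkin import (
    ConfusionMatrix,
    beecher_hs,
    binomial_individual_tests,
    cohens_kappa,
    lda_loo,
    nested_pdfa,
    pca_kaiser,
    per_individual_anova,
    sex_difference_lmes,
)

from _oracles import anova_f_bruteforce


class TestPcaKaiser:
    def test_dominant_direction_has_leading_eigenvalue_above_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 6))
        X[:, 0] *= np.sqrt(10)
        X[:, 1] = X[:, 0] + rng.normal(scale=0.3, size=200)  # correlated pair
        model, scores = pca_kaiser(X)
        assert model.eigenvalues[0] > 1
        assert model.eigenvalues[0] >= model.eigenvalues[-1]
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_eigenvalue_sum_equals_number_of_parameters(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8))
        model, _ = pca_kaiser(X)
        assert model.eigenvalues.sum() == pytest.approx(8.0)

    def test_training_scores_are_uncorrelated(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
        model, scores = pca_kaiser(X)
        if scores.shape[1] > 1:
            corr = np.corrcoef(scores.T)
            off = corr[~np.eye(scores.shape[1], dtype=bool)]
            assert np.max(np.abs(off)) < 1e-8

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_kaiser(df)


class TestLdaLoo:
    def _clusters(self, sep, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(size=(n, 3)), rng.normal(size=(n, 3)) + [sep, 0, 0]]
        )
        y = ["a"] * n + ["b"] * n
        return X, y

    def test_well_separated_clusters_classified_almost_perfectly(self):
        X, y = self._clusters(sep=10.0)
        original, loo = lda_loo(X, y)
        assert loo.accuracy_pct >= 99.0

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 3))
        y = rng.choice(["a", "b", "c"], size=300)
        _, loo = lda_loo(X, y)
        assert loo.accuracy_pct < 50.0  # chance about 33%

    def test_matches_sklearn_discriminant_predictions(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X, y = self._clusters(sep=2.0, seed=5)
        original, _ = lda_loo(X, y)
        ref = sklearn_lda().fit(X, y).predict(X)
        from vocalkin.signature_stats import _LDA

        ours = _LDA().fit(X, np.asarray(y)).predict(X)
        assert np.mean(ours == ref) > 0.99

    def test_loo_not_more_optimistic_than_resubstitution_on_average(self):
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [rng.normal(size=(8, 3)) + [1.2, 0, 0], rng.normal(size=(8, 3))]
            )
            y = ["a"] * 8 + ["b"] * 8
            original, loo = lda_loo(X, y)
            diffs.append(original.accuracy_pct - loo.accuracy_pct)
        assert np.mean(diffs) >= 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_loo(np.zeros((4, 2)), ["a"] * 4)


class TestNestedPdfa:
    def _nested_data(self, effect, n_ind=8, calls=8, seed=0):
        rng = np.random.default_rng(seed)
        inds = [f"i{k}" for k in range(n_ind)]
        sexes = ["F", "M"] * (n_ind // 2)
        X, sex_l, ind_l = [], [], []
        for ind, sx in zip(inds, sexes):
            centre = rng.normal(size=2) + (np.array([effect, 0.0]) if sx == "M" else 0.0)
            X.append(centre + rng.normal(scale=1.0, size=(calls, 2)))
            sex_l += [sx] * calls
            ind_l += [ind] * calls
        return np.vstack(X), sex_l, ind_l

    def test_strong_sex_effect_detected(self):
        X, sex_l, ind_l = self._nested_data(effect=4.0, seed=1)
        res = nested_pdfa(X, sex_l, ind_l, n_perm=99, n_selections=5, seed=2)
        assert res.p_value <= 0.05
        assert res.observed_pct > res.chance_pct

    def test_null_p_value_is_not_extreme(self):
        X, sex_l, ind_l = self._nested_data(effect=0.0, seed=3)
        res = nested_pdfa(X, sex_l, ind_l, n_perm=99, n_selections=5, seed=4)
        assert 0.0 < res.p_value <= 1.0

    def test_zero_permutations_rejected(self):
        X, sex_l, ind_l = self._nested_data(effect=1.0)
        with pytest.raises(ValueError, match="n_perm"):
            nested_pdfa(X, sex_l, ind_l, n_perm=0)

    def test_individual_with_mixed_test_levels_rejected(self):
        X, sex_l, ind_l = self._nested_data(effect=1.0)
        sex_l[0] = "M" if sex_l[0] == "F" else "F"
        with pytest.raises(ValueError, match="levels"):
            nested_pdfa(X, sex_l, ind_l, n_perm=10)

    def test_too_few_individuals_per_level_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        sex_l = ["F"] * 15 + ["M"] * 5
        ind_l = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
        with pytest.raises(ValueError, match="2 individuals"):
            nested_pdfa(X, sex_l, ind_l, n_perm=10)


class TestBinomialTests:
    def _confusion(self, counts):
        labels = [f"l{i}" for i in range(len(counts))]
        return ConfusionMatrix(labels=labels, counts=np.array(counts))

    def test_perfect_individual_closed_form(self):
        # 10/10 correct at chance 0.1 -> p = 0.1^10
        p = binomial_individual_tests(
            self._confusion([[10, 0], [0, 90]]), chance_rule=0.1
        )
        assert p["l0"] == pytest.approx(1e-10, rel=1e-6)

    def test_zero_correct_has_p_one(self):
        p = binomial_individual_tests(
            self._confusion([[0, 10], [0, 90]]), chance_rule=0.1
        )
        assert p["l0"] == pytest.approx(1.0)

    def test_matches_bruteforce_binomial_tail(self):
        p = binomial_individual_tests(
            self._confusion([[7, 3], [5, 25]]), chance_rule=0.25
        )
        oracle = sum(
            stats.binom.pmf(k, 10, 0.25) for k in range(7, 11)
        )
        assert p["l0"] == pytest.approx(oracle, rel=1e-10)

    def test_default_chance_is_class_prior(self):
        conf = self._confusion([[5, 5], [5, 85]])
        p_prior = binomial_individual_tests(conf)
        oracle = sum(stats.binom.pmf(k, 10, 0.1) for k in range(5, 11))
        assert p_prior["l0"] == pytest.approx(oracle, rel=1e-10)


class TestCohensKappa:
    def test_perfect_agreement(self):
        conf = ConfusionMatrix(["a", "b"], np.array([[10, 0], [0, 5]]))
        assert cohens_kappa(conf) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # counts proportional to products of the marginals
        conf = ConfusionMatrix(["a", "b"], np.array([[8, 2], [32, 8]]))
        assert cohens_kappa(conf) == pytest.approx(0.0)

    def test_hand_evaluated_2x2(self):
        conf = ConfusionMatrix(["a", "b"], np.array([[8, 2], [3, 7]]))
        # p_o = 15/20 = 0.75; p_e = (10*11 + 10*9)/400 = 0.5; kappa = 0.5
        assert cohens_kappa(conf) == pytest.approx(0.5)

    def test_permuted_labels_average_to_zero(self):
        rng = np.random.default_rng(6)
        kappas = []
        for _ in range(300):
            y = rng.choice(["a", "b"], size=40)
            pred = rng.permutation(y)
            counts = np.zeros((2, 2), dtype=int)
            for t, p in zip(y, pred):
                counts[int(t == "b"), int(p == "b")] += 1
            kappas.append(cohens_kappa(ConfusionMatrix(["a", "b"], counts)))
        assert abs(np.mean(kappas)) < 0.03

    def test_degenerate_matrix_signalled(self):
        conf = ConfusionMatrix(["a", "b"], np.array([[10, 0], [0, 0]]))
        with pytest.raises(ValueError):
            cohens_kappa(conf)


class TestBeecherHs:
    def test_uninformative_components_contribute_zero(self):
        # within == between variance ratio F == 1 for both groups
        x = np.array([0.0, 2.0, 1.0, 3.0])  # groups {0,2} and {1,3}: F = 1
        labels = ["a", "a", "b", "b"]
        assert beecher_hs(x[:, None], labels) == pytest.approx(0.0, abs=1e-12)

    def test_two_components_with_f_four_give_two_bits(self):
        # two groups of 2: means +-sqrt(2), within deviations +-1 -> F = 4
        m = np.sqrt(2.0)
        comp = np.array([m - 1, m + 1, -m - 1, -m + 1])
        X = np.column_stack([comp, comp])
        labels = ["a", "a", "b", "b"]
        assert beecher_hs(X, labels) == pytest.approx(2.0, rel=1e-9)

    def test_more_individual_variance_means_more_identity_information(self):
        rng = np.random.default_rng(7)
        def hs_for(sigma_ind):
            centres = rng.normal(scale=sigma_ind, size=(10, 4))
            X = np.repeat(centres, 12, axis=0) + rng.normal(size=(120, 4))
            labels = np.repeat([f"i{k}" for k in range(10)], 12)
            return beecher_hs(X, labels)
        assert hs_for(3.0) > hs_for(0.5)

    def test_doubling_independent_components_doubles_hs(self):
        rng = np.random.default_rng(8)
        centres = rng.normal(scale=2.0, size=(12, 8))
        X = np.repeat(centres, 10, axis=0) + rng.normal(size=(120, 8))
        labels = np.repeat([f"i{k}" for k in range(12)], 10)
        h4 = beecher_hs(X[:, :4], labels)
        h8 = beecher_hs(X, labels)
        assert h8 == pytest.approx(2 * h4, rel=0.25)


class TestPerIndividualAnova:
    def test_matches_bruteforce_sums_of_squares(self):
        feats = pd.DataFrame({"p1": [1.0, 2.0, 2.5, 4.0, 5.0, 7.0]})
        labels = ["a", "a", "b", "b", "c", "c"]
        table = per_individual_anova(feats, labels)
        samples = [np.array([1.0, 2.0]), np.array([2.5, 4.0]), np.array([5.0, 7.0])]
        assert table.loc["p1", "F"] == pytest.approx(anova_f_bruteforce(samples))
        assert table.loc["p1", "df_num"] == 2
        assert table.loc["p1", "df_den"] == 3

    def test_shifted_individual_is_strongly_significant(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 1))
        labels = np.repeat([f"i{k}" for k in range(6)], 10)
        X[labels == "i0"] += 10.0
        table = per_individual_anova(pd.DataFrame(X, columns=["p1"]), labels)
        assert table.loc["p1", "p"] < 0.001

    def test_constant_parameter_flagged(self):
        feats = pd.DataFrame({"flat": [1.0] * 6, "ok": [1, 2, 3, 4, 5, 6.0]})
        labels = ["a", "a", "b", "b", "c", "c"]
        table = per_individual_anova(feats, labels)
        assert np.isnan(table.loc["flat", "F"])
        assert np.isfinite(table.loc["ok", "F"])


class TestSexDifferenceLmes:
    def _dataset(self, beta, seed=0, n_ind=10, calls=8, n_params=3):
        rng = np.random.default_rng(seed)
        inds = [f"i{k}" for k in range(n_ind)]
        sexes = ["F", "M"] * (n_ind // 2)
        rows, sex_l, ind_l = [], [], []
        for ind, sx in zip(inds, sexes):
            base = rng.normal(scale=1.0, size=n_params)
            for _ in range(calls):
                x = base + rng.normal(scale=0.5, size=n_params)
                if sx == "M":
                    x = x + np.array([beta] + [0.0] * (n_params - 1))
                rows.append(x)
                sex_l.append(sx)
                ind_l.append(ind)
        return pd.DataFrame(rows, columns=[f"p{i}" for i in range(n_params)]), sex_l, ind_l

    def test_large_effect_on_first_parameter_only(self):
        feats, sex_l, ind_l = self._dataset(beta=5.0, seed=1)
        table = sex_difference_lmes(feats, sex_l, ind_l)
        assert table.loc["p0", "p"] < 0.01
        assert table.loc["p0", "estimate"] == pytest.approx(5.0, abs=1.5)

    def test_null_type_one_error_close_to_nominal(self):
        hits = total = 0
        for seed in range(20):
            feats, sex_l, ind_l = self._dataset(beta=0.0, seed=seed, n_params=8)
            table = sex_difference_lmes(feats, sex_l, ind_l)
            hits += int((table["p"] < 0.05).sum())
            total += len(table)
        # 160 null tests at alpha = 0.05: expect about 8 rejections
        lo, hi = stats.binom.interval(0.999, total, 0.05)
        assert lo <= hits <= hi

    def test_constant_parameter_skipped(self):
        feats, sex_l, ind_l = self._dataset(beta=1.0, seed=2)
        feats["flat"] = 1.0
        table = sex_difference_lmes(feats, sex_l, ind_l)
        assert np.isnan(table.loc["flat", "estimate"])
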