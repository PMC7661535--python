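import numpy as np
import pandas as pd
import pytest

from ppgage.cohort_ml import (COVARIATE_COLUMNS, dichotomize_age,
                              encode_covariates, evaluate, fit_classifier,
                              ridge_rank, robust_standardize,
                              sex_stratified_trend, split_cohort)
from ppgage.errors import PPGAgeError
from ppgage.features import FEATURE_NAMES

from .oracles import pairwise_auc


def synthetic_table(n, seed=0, ppg_effect=1.0, female_age_offset=0.0,
                    noise=6.0, tpr_noise=0.02, smoking_age_link=0.0):
    """Feature-table stand-in with a planted age signal in a and tpr."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 79, n)
    sex = rng.choice(["male", "female"], n)
    if female_age_offset:
        age = np.where(sex == "female",
                       np.maximum(18.0, age + female_age_offset), age)
    df = pd.DataFrame({c: rng.standard_normal(n) for c in FEATURE_NAMES})
    df["a"] = 200 - ppg_effect * 1.5 * age + noise * rng.standard_normal(n)
    df["tpr"] = (0.2 + ppg_effect * 0.005 * age
                 + tpr_noise * rng.standard_normal(n))
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df["sex"] = sex
    df["weight"] = rng.normal(75, 12, n)
    df["height"] = rng.normal(172, 9, n)
    p_smoke = np.clip(0.35 + smoking_age_link * ((age - 18) / 61 - 0.5),
                      0.02, 0.98)
    df["smoking"] = np.where(rng.random(n) < p_smoke, "yes", "no")
    df["age"] = age
    df["label"] = [dichotomize_age(a) for a in age]
    return df


class TestDichotomize:
    @pytest.mark.parametrize("age,expected", [
        (30.0, 1), (18.0, 1), (38.0, 1),
        (65.0, 0), (60.0, 0), (79.0, 0),
        (50.0, None), (39.0, None), (80.0, None), (17.0, None), (None, None),
    ])
    def test_bands(self, age, expected):
        assert dichotomize_age(age) == expected


class TestSplit:
    def test_printed_sizes(self):
        cohort = synthetic_table(3612, seed=1)
        train, test = split_cohort(cohort, test_fraction=0.25, seed=0)
        assert (len(train), len(test)) == (2709, 903)
        assert set(train.index).isdisjoint(test.index)

    def test_same_seed_identical(self):
        cohort = synthetic_table(400, seed=2)
        a = split_cohort(cohort, seed=5)
        b = split_cohort(cohort, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_age_distribution_kept_similar(self):
        cohort = synthetic_table(2000, seed=3)
        train, test = split_cohort(cohort, seed=0)
        deciles = pd.qcut(cohort["age"], 10, labels=False)
        for d in range(10):
            share = (deciles[test.index] == d).sum() / (deciles == d).sum()
            assert share == pytest.approx(0.25, abs=0.05)
        # the label mix of the two sets differs by < 5 percentage points
        p_train = (train["label"] == 1).mean()
        p_test = (test["label"] == 1).mean()
        assert abs(p_train - p_test) < 0.05

    def test_too_small_errors(self):
        with pytest.raises(PPGAgeError):
            split_cohort(synthetic_table(6, seed=0))


class TestRobustStandardize:
    def test_hand_case(self):
        train = pd.DataFrame({"x": [3.0, 4, 5, 6, 7]})  # median 5, IQR 2
        apply_to = pd.DataFrame({"x": [7.0]})
        _, out, params = robust_standardize(train, apply_to)
        assert out["x"].iloc[0] == pytest.approx(1.0)
        assert params.median["x"] == 5.0
        assert params.iqr["x"] == 2.0

    def test_self_standardization(self):
        rng = np.random.default_rng(4)
        train = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        z, _, _ = robust_standardize(train)
        for c in "abc":
            assert z[c].median() == pytest.approx(0.0, abs=1e-12)
            assert (z[c].quantile(0.75) - z[c].quantile(0.25)) == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        train = pd.DataFrame({"x": [1.0, 2, 3, 4], "k": [5.0] * 4})
        with pytest.warns(UserWarning, match="zero-IQR"):
            z, _, params = robust_standardize(train)
        assert (z["k"] == 0).all()
        assert params.degenerate == ["k"]

    def test_parameters_learned_on_train_only(self):
        train = pd.DataFrame({"x": [0.0, 1, 2, 3, 4]})
        test = pd.DataFrame({"x": [100.0, 200.0]})
        _, _, params = robust_standardize(train, test)
        assert params.source == "train"
        assert params.median["x"] == 2.0


class TestRidgeRank:
    def _planted(self, n=500, p=10, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"x{i + 1}" for i in range(p)])
        y = 2 * X["x1"] - 2 * X["x2"] + rng.standard_normal(n)
        label = (y > y.median()).astype(int)
        return X, y.to_numpy(), label.to_numpy()

    def test_planted_signal_recovered(self):
        X, y, label = self._planted()
        ranking = ridge_rank(X, y, label, n_reps=25, seed=0)
        assert set(ranking.top(2)) == {"x1", "x2"}

    def test_final_score_is_sum_of_means(self):
        X, y, label = self._planted(n=200)
        ranking = ridge_rank(X, y, label, n_reps=10, seed=1)
        t = ranking.table
        np.testing.assert_allclose(t["final"], t["linear_rank"] + t["logistic_rank"])
        p = len(X.columns)
        assert ((t["linear_rank"] >= 1) & (t["linear_rank"] <= p)).all()
        assert ((t["final"] >= 2) & (t["final"] <= 2 * p)).all()

    def test_pure_noise_is_unstable(self):
        # two independently simulated null datasets give unrelated rankings
        tables = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((300, 10)),
                             columns=[f"x{i}" for i in range(10)])
            y = rng.standard_normal(300)
            label = rng.integers(0, 2, 300)
            tables.append(ridge_rank(X, y, label, n_reps=10,
                                     seed=seed).table.set_index("variable"))
        r1, r2 = tables
        rho = r1["final"].corr(r2.loc[r1.index, "final"], method="spearman")
        assert rho < 0.5

    def test_planted_a_tpr_rank_top6_with_covariates(self):
        # mirrors the published ranking-table structure: 38 features + 4
        # covariates ranked jointly; the planted a/tpr effects surface
        cohort = synthetic_table(800, seed=7, noise=20.0, tpr_noise=0.05,
                                 smoking_age_link=0.4)
        labelled = cohort.dropna(subset=["label"])
        X = pd.concat([labelled[list(FEATURE_NAMES)],
                       encode_covariates(labelled)], axis=1)
        Xs, _, _ = robust_standardize(X)
        ranking = ridge_rank(Xs, labelled["age"].to_numpy(),
                             labelled["label"].to_numpy(), n_reps=25, seed=0)
        top6 = ranking.top(6)
        assert "a" in top6
        assert "tpr" in top6

    def test_waveform_cohort_recovers_planted_clusters(self):
        # through the full signal pipeline, the top of the ranking is
        # dominated by stiffness-driven (SDPPG) and randomness-driven
        # (RR-irregularity) features
        from ppgage.features import RRDIFF_FEATURES, SDPPG_FEATURES
        from ppgage.io_h4h import assemble_cohort
        from ppgage.synthetic import STRONG_EFFECTS, generate_cohort

        recs, _ = generate_cohort(250, STRONG_EFFECTS, seed=21)
        cohort, _ = assemble_cohort(recs)
        labelled = cohort.dropna(subset=["label"])
        X = pd.concat([labelled[list(FEATURE_NAMES)],
                       encode_covariates(labelled)], axis=1)
        Xs, _, _ = robust_standardize(X)
        ranking = ridge_rank(Xs, labelled["age"].to_numpy(),
                             labelled["label"].to_numpy(), n_reps=10, seed=3)
        top6 = set(ranking.top(6))
        irregularity = {"tpr", "tpr_diff", "kurtosisRR", "skewnessRR"}
        assert top6 & set(SDPPG_FEATURES)
        assert top6 & irregularity

    def test_single_variable_errors(self):
        X = pd.DataFrame({"x": np.random.default_rng(0).standard_normal(50)})
        with pytest.raises(PPGAgeError):
            ridge_rank(X, X["x"].to_numpy(), (X["x"] > 0).to_numpy().astype(int))


class TestClassifier:
    def test_separable_clusters(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(np.vstack((rng.normal(0, 0.2, (40, 2)),
                                    rng.normal(5, 0.2, (40, 2)))),
                         columns=["u", "v"])
        y = np.repeat([0, 1], 40)
        clf = fit_classifier(X, y, seed=0)
        assert (clf.predict(X.to_numpy()) == y).mean() == 1.0

    def test_tuning_deterministic(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = (X["a"] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        a = fit_classifier(X, y, seed=3)
        b = fit_classifier(X, y, seed=3)
        assert a.get_params() == b.get_params()

    def test_single_class_errors(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        with pytest.raises(PPGAgeError):
            fit_classifier(X, np.ones(4, dtype=int), seed=0)


class _Scores:
    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def decision_function(self, X):
        return self._scores


class TestEvaluate:
    def test_perfect_separation(self):
        report = evaluate(_Scores([0.9, 0.8, 0.4, 0.3]), np.zeros((4, 1)),
                          [1, 1, 0, 0])
        assert report.auc == pytest.approx(1.0)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_worked_half_case(self):
        report = evaluate(_Scores([0.9, 0.3, 0.8, 0.4]), np.zeros((4, 1)),
                          [1, 1, 0, 0])
        assert report.auc == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(2000)
        labels = np.repeat([0, 1], 1000)
        report = evaluate(_Scores(scores), np.zeros((2000, 1)), labels)
        assert report.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.standard_normal(n), 2)
            report = evaluate(_Scores(scores), np.zeros((n, 1)), labels)
            assert report.auc == pytest.approx(pairwise_auc(scores, labels))

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        report = evaluate(_Scores(scores), np.zeros((100, 1)), labels)
        assert np.all(np.diff(report.fpr) >= 0)
        assert np.all(np.diff(report.tpr) >= 0)
        assert (report.fpr[0], report.tpr[0]) == (0.0, 0.0)
        assert (report.fpr[-1], report.tpr[-1]) == (1.0, 1.0)
        assert report.auc == pytest.approx(np.trapezoid(report.tpr, report.fpr))

    def test_single_class_test_errors(self):
        with pytest.raises(PPGAgeError):
            evaluate(_Scores([1.0, 2.0]), np.zeros((2, 1)), [1, 1])


class TestCompareModels:
    def test_planted_ppg_effect_beats_covariates(self):
        from ppgage.cohort_ml import compare_models

        cohort = synthetic_table(1200, seed=11, ppg_effect=1.0)
        train, test = split_cohort(cohort, seed=0)
        reports = compare_models(train, test, seed=0, models=("i", "iii"))
        assert reports["iii"].auc > reports["i"].auc
        assert reports["iii"].auc > 0.9

    def test_null_ppg_effect_matches_covariates(self):
        from ppgage.cohort_ml import compare_models

        cohort = synthetic_table(1200, seed=13, ppg_effect=0.0)
        train, test = split_cohort(cohort, seed=0)
        reports = compare_models(train, test, seed=0, models=("i", "iii"))
        assert abs(reports["iii"].auc - reports["i"].auc) < 0.1

    def test_full_model_fits_train_at_least_as_well(self):
        from ppgage.cohort_ml import compare_models

        cohort = synthetic_table(600, seed=17)
        train, _ = split_cohort(cohort, seed=0)
        # evaluate both models on the training set itself
        reports = compare_models(train, train, seed=0, models=("iii", "v"))
        assert reports["v"].auc >= reports["iii"].auc - 1e-9

    def test_label_permutation_null(self):
        from ppgage.cohort_ml import compare_models

        cohort = synthetic_table(1200, seed=19)
        rng = np.random.default_rng(0)
        labelled = cohort.dropna(subset=["label"]).copy()
        labelled["label"] = rng.permutation(labelled["label"].to_numpy())
        train, test = split_cohort(labelled, seed=0)
        reports = compare_models(train, test, seed=0, models=("iii",))
        assert 0.4 <= reports["iii"].auc <= 0.6


class TestSexTrend:
    def test_smoother_reproduces_linear_predictions(self):
        # noiseless linear link: predictions equal age, curves equal the line
        cohort = synthetic_table(800, seed=23, noise=0.0)
        cohort["tpr"] = 0.2 + 0.005 * cohort["age"]  # kill tpr noise too
        train, test = split_cohort(cohort, seed=0)
        curves = sex_stratified_trend(train, test, seed=0)
        for sex, curve in curves.items():
            np.testing.assert_allclose(curve["predicted_age"], curve["age"],
                                       rtol=0.01)

    def test_identical_sexes_small_gap(self):
        cohort = synthetic_table(4000, seed=29, female_age_offset=0.0,
                                 noise=30.0, tpr_noise=0.15)
        train, test = split_cohort(cohort, seed=0)
        curves = sex_stratified_trend(train, test, seed=0, lowess_frac=0.7)
        gap = np.abs(curves["male"]["predicted_age"].to_numpy()
                     - curves["female"]["predicted_age"].to_numpy())
        assert gap.max() < 2.0

    def test_planted_offset_lowers_female_curve(self):
        # high feature noise -> attenuated regression slope, which is what
        # turns the shifted female age distribution into a visible gap
        cohort = synthetic_table(4000, seed=31, female_age_offset=-5.0,
                                 noise=30.0, tpr_noise=0.15)
        train, test = split_cohort(cohort, seed=0)
        curves = sex_stratified_trend(train, test, seed=0, lowess_frac=0.7)
        gap = (curves["male"]["predicted_age"].to_numpy()
               - curves["female"]["predicted_age"].to_numpy())
        assert np.all(gap > 0)


class TestEncodeCovariates:
    def test_binary_encoding(self):
        df = pd.DataFrame({"sex": ["male", "female"], "weight": [80.0, 60.0],
                           "height": [180.0, 165.0], "smoking": ["yes", "no"]})
        enc = encode_covariates(df)
        assert list(enc.columns) == list(COVARIATE_COLUMNS)
        assert enc["sex"].tolist() == [1.0, 0.0]
        assert enc["smoking"].tolist() == [1.0, 0.0]
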