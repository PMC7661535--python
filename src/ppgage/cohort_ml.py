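"""Cohort-level statistics: age dichotomization, stratified splitting,
robust standardization, repeated ridge feature ranking, SVM classification,
ROC evaluation, and the sex-stratified predicted-age trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVC
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._ridge import linear_ridge_cv, logistic_ridge_cv
from .errors import PPGAgeError
from .features import FEATURE_NAMES

__all__ = [
    "RankingTable",
    "EvalReport",
    "StandardizationParams",
    "COVARIATE_COLUMNS",
    "dichotomize_age",
    "encode_covariates",
    "split_cohort",
    "robust_standardize",
    "ridge_rank",
    "fit_classifier",
    "evaluate",
    "compare_models",
    "sex_stratified_trend",
]

COVARIATE_COLUMNS = ("sex", "weight", "height", "smoking")

#: ridge penalty grid: 30 log-spaced values in [1e-3, 1e3]
PENALTY_GRID = np.logspace(-3, 3, 30)


def dichotomize_age(age: float | None):
    """Map age to the binary vascular-aging label.

    18–38 years -> 1 (young, healthy vascular aging proxy); 60–79 -> 0
    (old, non-HVA); anything else (including missing) -> ``None``.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return None
    if 18.0 <= age <= 38.0:
        return 1
    if 60.0 <= age <= 79.0:
        return 0
    return None


def encode_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate block: sex male=1/female=0, smoking yes=1/no=0."""
    out = pd.DataFrame(index=cohort.index)
    out["sex"] = (cohort["sex"] == "male").astype(float)
    out["weight"] = cohort["weight"].astype(float)
    out["height"] = cohort["height"].astype(float)
    out["smoking"] = (cohort["smoking"] == "yes").astype(float)
    return out


def split_cohort(cohort: pd.DataFrame, test_fraction: float = 0.25,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test split stratified by age decile.

    The total test size is ``round(n * test_fraction)``; per-stratum test
    counts are allocated proportionally with largest remainders so the age
    distribution of the two sets stays similar.  Falls back to a global
    random split when a stratum would be empty.
    """
    n = len(cohort)
    if n < 8:
        raise PPGAgeError("cohort too small to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(n * test_fraction))
    try:
        deciles = pd.qcut(cohort["age"], 10, labels=False, duplicates="drop")
        if deciles.nunique() < 2:
            raise ValueError("degenerate age distribution")
    except ValueError:
        warnings.warn("age stratification failed; using a global random split")
        perm = rng.permutation(n)
        test_idx = cohort.index[perm[:n_test]]
        return cohort.drop(test_idx), cohort.loc[test_idx]

    sizes = deciles.value_counts().sort_index()
    exact = sizes * n_test / n
    base = np.floor(exact).astype(int)
    remainder = n_test - int(base.sum())
    order = np.argsort(-(exact - base).to_numpy())
    take = base.to_numpy().copy()
    take[order[:remainder]] += 1
    test_rows = []
    for (stratum, size), k in zip(sizes.items(), take):
        members = cohort.index[deciles == stratum].to_numpy()
        chosen = rng.choice(members, size=k, replace=False)
        test_rows.extend(chosen)
    test_idx = pd.Index(test_rows)
    return cohort.drop(test_idx), cohort.loc[test_idx]


@dataclass
class StandardizationParams:
    """Median/IQR per column, learned on the training set only."""

    median: pd.Series
    iqr: pd.Series
    degenerate: list = field(default_factory=list)
    source: str = "train"  # provenance tag; never computed on test data


def robust_standardize(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, StandardizationParams]:
    """Subtract the column median and divide by the interquartile range.

    Parameters come from ``train`` only.  Zero-IQR columns are flagged and
    standardized to all-zero with a warning.
    """
    median = train.median()
    iqr = train.quantile(0.75) - train.quantile(0.25)
    degenerate = list(iqr.index[iqr == 0])
    if degenerate:
        warnings.warn(f"zero-IQR columns standardized to 0: {degenerate}")
    safe_iqr = iqr.replace(0, 1.0)
    params = StandardizationParams(median=median, iqr=iqr, degenerate=degenerate)

    def apply(df: pd.DataFrame) -> pd.DataFrame:
        z = (df - median) / safe_iqr
        z[degenerate] = 0.0
        return z

    return apply(train), (apply(apply_to) if apply_to is not None else None), params


@dataclass
class RankingTable:
    """Averaged ridge rankings; lower scores mean more relevant variables."""

    table: pd.DataFrame  # columns: variable, linear_rank, logistic_rank, final
    per_rep_linear: np.ndarray  # (n_reps, p) ranks
    per_rep_logistic: np.ndarray

    def top(self, k: int) -> list[str]:
        return list(self.table["variable"].head(k))


def _rank_abs_coefs(coefs: np.ndarray) -> np.ndarray:
    """Rank 1 = largest |coefficient|; average ranks on ties."""
    return rankdata(-np.abs(coefs))


def ridge_rank(
    features: pd.DataFrame,
    age: np.ndarray,
    label: np.ndarray,
    n_reps: int = 100,
    seed: int = 0,
    subsample: float = 2.0 / 3.0,
    cv_folds: int = 10,
) -> RankingTable:
    """Repeated ridge-regression relevance ranking.

    Per repetition: draw ``subsample`` of the rows without replacement; fit
    a linear ridge on continuous age and a logistic ridge on the binary
    label, each with its penalty tuned by ``cv_folds``-fold CV over
    :data:`PENALTY_GRID`; rank variables by decreasing absolute coefficient.
    Mean ranks per model are summed into the final score (ascending order =
    most relevant first).
    """
    X = np.asarray(features, dtype=float)
    age = np.asarray(age, dtype=float)
    label = np.asarray(label, dtype=float)
    n, p = X.shape
    if p < 2:
        raise PPGAgeError("need at least 2 variables to rank")
    rng = np.random.default_rng(seed)
    lin_ranks = np.empty((n_reps, p))
    log_ranks = np.empty((n_reps, p))
    m = min(n, max(int(round(n * subsample)), cv_folds))
    folds = min(cv_folds, m)
    for rep in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        Xs, ys, ls = X[idx], age[idx], label[idx]
        lin_coef, _, _ = linear_ridge_cv(Xs, ys, PENALTY_GRID, folds=folds,
                                         rng=rng)
        lin_ranks[rep] = _rank_abs_coefs(lin_coef)
        log_coef, _, _ = logistic_ridge_cv(Xs, ls, PENALTY_GRID, folds=folds,
                                           rng=rng)
        log_ranks[rep] = _rank_abs_coefs(log_coef)
    mean_lin = lin_ranks.mean(axis=0)
    mean_log = log_ranks.mean(axis=0)
    table = pd.DataFrame({
        "variable": list(features.columns),
        "linear_rank": mean_lin,
        "logistic_rank": mean_log,
        "final": mean_lin + mean_log,
    }).sort_values("final", ignore_index=True)
    return RankingTable(table, lin_ranks, log_ranks)


def fit_classifier(train_X: pd.DataFrame, labels: np.ndarray, seed: int = 0):
    """RBF-kernel SVM tuned by 3-fold CV grid search on the training set."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise PPGAgeError("training labels contain a single class")
    grid = {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": [f * (1.0 / train_X.shape[1]) for f in (0.1, 1.0, 10.0)],
    }
    cv = KFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, scoring="roc_auc")
    search.fit(np.asarray(train_X, dtype=float), y)
    return search.best_estimator_


@dataclass
class EvalReport:
    """Classification metrics on a held-out test set."""

    model: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    n_test: int


def evaluate(classifier, test_X, test_y, model_name: str = "model") -> EvalReport:
    """ROC/AUC (trapezoidal) plus sens/spec at the Youden-optimal threshold."""
    from sklearn.metrics import roc_curve

    y = np.asarray(test_y)
    if len(np.unique(y)) < 2:
        raise PPGAgeError("test labels contain a single class")
    scores = classifier.decision_function(np.asarray(test_X, dtype=float))
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    k = int(np.argmax(youden))
    return EvalReport(
        model=model_name, fpr=fpr, tpr=tpr, auc=auc,
        sensitivity=float(tpr[k]), specificity=float(1.0 - fpr[k]),
        n_test=int(y.size),
    )


MODEL_VARIABLES = {
    "i": list(COVARIATE_COLUMNS),
    "ii": ["a", "tpr"],
    "iii": list(COVARIATE_COLUMNS) + ["a", "tpr"],
    "v": list(COVARIATE_COLUMNS) + list(FEATURE_NAMES),
}


def _design(cohort: pd.DataFrame, variables) -> pd.DataFrame:
    cov = encode_covariates(cohort)
    blocks = []
    for var in variables:
        if var in cov.columns:
            blocks.append(cov[var])
        else:
            blocks.append(cohort[var].astype(float))
    return pd.concat(blocks, axis=1, keys=variables)


def compare_models(train: pd.DataFrame, test: pd.DataFrame, seed: int = 0,
                   models=("i", "ii", "iii", "v")) -> dict[str, EvalReport]:
    """Fit and evaluate the covariate/PPG-feature model family on one split.

    Models: (i) covariates only, (ii) the two best PPG features (a, tpr),
    (iii) covariates plus those two, (v) covariates plus all 38 features.
    All use the identical train/test split and labelled subjects only.
    """
    train_l = train.dropna(subset=["label"])
    test_l = test.dropna(subset=["label"])
    reports = {}
    for model in models:
        variables = MODEL_VARIABLES[model]
        Xtr = _design(train_l, variables)
        Xte = _design(test_l, variables)
        Xtr_s, Xte_s, _ = robust_standardize(Xtr, Xte)
        clf = fit_classifier(Xtr_s, train_l["label"].astype(int), seed=seed)
        reports[model] = evaluate(clf, Xte_s, test_l["label"].astype(int),
                                  model_name=model)
    return reports


def sex_stratified_trend(
    train: pd.DataFrame, test: pd.DataFrame, seed: int = 0, n_grid: int = 25,
    lowess_frac: float = 0.6,
) -> dict[str, pd.DataFrame]:
    """LOWESS curves of predicted age vs true age, per sex.

    The linear model ``age ~ a + tpr + covariates`` is fitted on the full
    training set (all ages); test-set predictions are smoothed per sex and
    sampled on a common age grid spanning the overlap of the two sexes.
    """
    import statsmodels.api as sm

    variables = ["a", "tpr"] + list(COVARIATE_COLUMNS)
    Xtr = _design(train, variables)
    Xte = _design(test, variables)
    Xtr_s, Xte_s, _ = robust_standardize(Xtr, Xte)
    ols = sm.OLS(train["age"].to_numpy(float), sm.add_constant(Xtr_s)).fit()
    predicted = np.asarray(ols.predict(sm.add_constant(Xte_s)), dtype=float)

    curves: dict[str, pd.DataFrame] = {}
    sexes = [s for s in ("female", "male") if (test["sex"] == s).any()]
    if len(sexes) < 2:
        warnings.warn("a sex is absent from the test set; its curve is omitted")
    lo = max(test.loc[test["sex"] == s, "age"].min() for s in sexes)
    hi = min(test.loc[test["sex"] == s, "age"].max() for s in sexes)
    grid = np.linspace(lo, hi, n_grid)
    for sex in sexes:
        mask = (test["sex"] == sex).to_numpy()
        fitted = lowess(predicted[mask], test.loc[mask, "age"].to_numpy(float),
                        frac=lowess_frac, return_sorted=True)
        curves[sex] = pd.DataFrame({
            "age": grid,
            "predicted_age": np.interp(grid, fitted[:, 0], fitted[:, 1]),
        })
    return curves
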