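"""Case-control multivariate pattern analysis.

Per spatial scale: univariate F-score feature ranking (computed on
training folds only), SVM hyperparameter grid search by inner
cross-validation, subject-level k-fold outer cross-validation over a
series of feature fractions, permutation inference for the resulting
accuracy, consensus linear weights across folds, and correlation of
consensus features with clinical symptom scores.

The default hyperparameter grids are the full study grids: C-SVC with
C in 1:5:100 (20 values) and nu-SVC with nu in 0.2:0.1:0.7 (6 values),
each crossed with linear, polynomial and RBF kernels (78 combinations).
Reduced grids for quick desk-scale runs are plain constructor arguments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, NuSVC
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

KERNEL_ORDER = ("linear", "poly", "rbf")
DEFAULT_C_GRID = tuple(range(1, 100, 5))  # 20 values
DEFAULT_NU_GRID = tuple(round(0.2 + 0.1 * i, 1) for i in range(6))  # 6 values


@dataclass
class FeatureDataset:
    """Subjects x features matrix with binary labels (1 = patient)."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    scale: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.subject_ids):
            raise ValueError("X, y and subject_ids must align")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject IDs must be unique")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")


@dataclass
class CVConfig:
    """Cross-validation and grid-search configuration (defaults = study grids)."""

    n_folds: int = 10
    feature_fractions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    svm_types: tuple[str, ...] = ("c_svc", "nu_svc")
    kernels: tuple[str, ...] = KERNEL_ORDER
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.feature_fractions):
            raise ValueError("feature fractions must lie in (0, 1]")
        unknown = set(self.svm_types) - {"c_svc", "nu_svc"}
        if unknown:
            raise ValueError(f"unknown svm types: {unknown}")
        unknown = set(self.kernels) - set(KERNEL_ORDER)
        if unknown:
            raise ValueError(f"unknown kernels: {unknown}")

    def grid(self) -> list[tuple[str, str, float]]:
        """Enumerate (kernel, svm_type, penalty) in the documented tie-break
        order: linear < poly < rbf, C-SVC before nu-SVC, smaller penalty first."""
        combos = []
        for kernel in [k for k in KERNEL_ORDER if k in self.kernels]:
            if "c_svc" in self.svm_types:
                combos.extend(("c_svc", kernel, c) for c in self.c_grid)
            if "nu_svc" in self.svm_types:
                combos.extend(("nu_svc", kernel, nu) for nu in self.nu_grid)
        return [(k, t, p) for (t, k, p) in combos]


def fscore(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-group one-way ANOVA F statistic per feature.

    F = MS_between / MS_within. Features with zero within-group variance and
    a nonzero group-mean difference get +inf (rank first); features with no
    variance at all get 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    if len(groups) < 2:
        raise ValueError("need two groups to compute F-scores")
    n = len(y)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in groups:
        sub = X[y == g]
        if sub.shape[0] < 2:
            raise ValueError("each group needs at least 2 subjects")
        ssb += sub.shape[0] * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    msb = ssb / (len(groups) - 1)
    msw = ssw / (n - len(groups))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[(msw == 0) & (msb > 0)] = np.inf
    f[(msw == 0) & (msb == 0)] = 0.0
    return f


def select_features(f: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the ceil(fraction * n) largest F-scores.

    Ties are broken by ascending feature index (stable, deterministic).
    Returned indices are sorted ascending.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    f = np.asarray(f, dtype=float)
    n_keep = math.ceil(fraction * len(f))
    order = np.lexsort((np.arange(len(f)), -f))
    return np.sort(order[:n_keep])


def _make_estimator(svm_type: str, kernel: str, penalty: float):
    if svm_type == "c_svc":
        return SVC(kernel=kernel, C=penalty, gamma="scale")
    return NuSVC(kernel=kernel, nu=penalty, gamma="scale")


def grid_search_train(X_train: np.ndarray, y_train: np.ndarray, config: CVConfig):
    """Pick SVM hyperparameters by inner CV on the training set and refit.

    Evaluates every (svm_type, kernel, penalty) combination by stratified
    inner cross-validation mean accuracy; ties keep the first combination in
    the enumeration order. Returns (fitted model, params dict, inner accuracy).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    n_splits = max(2, min(config.inner_folds, int(np.bincount(y_train).min())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X_train, y_train))

    best_acc, best_combo = -1.0, None
    for kernel, svm_type, penalty in config.grid():
        accs = []
        for tr, va in folds:
            if len(np.unique(y_train[tr])) < 2:
                logger.warning("inner fold with a single class skipped")
                continue
            model = _make_estimator(svm_type, kernel, penalty)
            try:
                model.fit(X_train[tr], y_train[tr])
            except ValueError:
                # e.g. infeasible nu for this class balance
                continue
            accs.append(float((model.predict(X_train[va]) == y_train[va]).mean()))
        mean_acc = float(np.mean(accs)) if accs else -np.inf
        if mean_acc > best_acc:
            best_acc, best_combo = mean_acc, (kernel, svm_type, penalty)

    if best_combo is None:
        raise RuntimeError("no hyperparameter combination could be fitted")
    kernel, svm_type, penalty = best_combo
    model = _make_estimator(svm_type, kernel, penalty)
    model.fit(X_train, y_train)
    params = {"kernel": kernel, "svm_type": svm_type, "penalty": penalty}
    return model, params, best_acc


@dataclass
class CVResult:
    """Outcome of the outer cross-validation."""

    fold_accuracies: pd.DataFrame  # rows = folds, columns = feature fractions
    best_fraction: float
    accuracy: float  # mean over folds at the best fraction
    pooled_accuracy: float  # pooled held-out predictions at the best fraction
    selected_features: list[np.ndarray]  # per fold, at the best fraction
    fold_weights: list[np.ndarray | None]  # per fold |features|-length linear weights
    fold_params: list[dict]
    n_features: int


def fit_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fraction: float,
    config: CVConfig,
):
    """Fit one outer fold at one feature fraction.

    Feature scoring, selection and the hyperparameter search see training
    subjects only; held-out subjects are touched exactly once, at
    prediction time. Returns (accuracy, selected indices, params,
    full-length weight vector or None).
    """
    f = fscore(X[train_idx], y[train_idx])
    sel = select_features(f, fraction)
    model, params, _ = grid_search_train(X[np.ix_(train_idx, sel)], y[train_idx], config)
    acc = float((model.predict(X[np.ix_(test_idx, sel)]) == y[test_idx]).mean())
    weights = None
    if params["kernel"] == "linear":
        weights = np.zeros(X.shape[1])
        weights[sel] = model.coef_[0]
    return acc, sel, params, weights


def run_cv(dataset: FeatureDataset, config: CVConfig) -> CVResult:
    """Subject-level k-fold cross-validation over all feature fractions.

    Folds partition subjects (stratified by group). For every fold and
    fraction, features and hyperparameters come from the training subjects
    alone. The fraction with the best mean held-out accuracy is reported;
    ties go to the smaller fraction.
    """
    X, y = dataset.X, dataset.y
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    seen: set[int] = set()
    for _, test in folds:
        overlap = seen & set(test.tolist())
        if overlap:
            raise ValueError(f"subjects {overlap} appear in two test folds (leakage)")
        seen |= set(test.tolist())

    fractions = sorted(config.feature_fractions)
    acc = np.zeros((len(folds), len(fractions)))
    records: dict[float, list] = {fr: [] for fr in fractions}
    for i, (train, test) in enumerate(folds):
        for j, fr in enumerate(fractions):
            a, sel, params, w = fit_fold(X, y, train, test, fr, config)
            acc[i, j] = a
            records[fr].append((a, sel, params, w, test))

    mean_acc = acc.mean(axis=0)
    best_j = int(np.argmax(mean_acc))  # argmax keeps the first (smaller) fraction on ties
    best_fraction = fractions[best_j]
    best_records = records[best_fraction]

    pooled_correct = 0
    for (a, _, _, _, test) in best_records:
        pooled_correct += a * len(test)
    pooled_accuracy = pooled_correct / len(y)

    return CVResult(
        fold_accuracies=pd.DataFrame(acc, columns=[str(f) for f in fractions]),
        best_fraction=best_fraction,
        accuracy=float(mean_acc[best_j]),
        pooled_accuracy=float(pooled_accuracy),
        selected_features=[sel for (_, sel, _, _, _) in best_records],
        fold_weights=[w for (_, _, _, w, _) in best_records],
        fold_params=[p for (_, _, p, _, _) in best_records],
        n_features=X.shape[1],
    )


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float


def permutation_test(dataset: FeatureDataset, config: CVConfig, B: int = 5000) -> PermutationResult:
    """Permutation inference for the cross-validated accuracy.

    Each of the B permutations shuffles the subject labels and re-runs the
    *entire* pipeline (feature scoring, selection, grid search, CV).
    p = (1 + #{null >= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = run_cv(dataset, config).accuracy
    rng = np.random.default_rng(config.seed)
    null = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(dataset.y)
        shuffled = FeatureDataset(dataset.X, y_perm, dataset.subject_ids, dataset.scale)
        null[b] = run_cv(shuffled, config).accuracy
    p = (1 + int((null >= observed).sum())) / (B + 1)
    return PermutationResult(observed, null, p)


def consensus_weights(cv_result: CVResult, top_fraction: float = 0.2) -> np.ndarray:
    """Consensus discriminative features across folds (linear kernel only).

    Intersects the features selected in every fold, averages absolute
    linear SVM weights over folds, and returns the indices of the top
    ``top_fraction`` by mean |w| (ceil count, ties to the lower index).
    Refuses explicitly when any fold chose a non-linear kernel, since
    feature weights cannot be read off non-linear machines.
    """
    for params in cv_result.fold_params:
        if params["kernel"] != "linear":
            raise ValueError(
                "consensus weights require a linear kernel in every fold; "
                f"fold used {params['kernel']!r}"
            )
    common = set(cv_result.selected_features[0].tolist())
    for sel in cv_result.selected_features[1:]:
        common &= set(sel.tolist())
    if not common:
        return np.array([], dtype=int)
    common_idx = np.array(sorted(common))
    mean_abs = np.mean([np.abs(w[common_idx]) for w in cv_result.fold_weights], axis=0)
    n_keep = math.ceil(top_fraction * len(common_idx))
    order = np.lexsort((common_idx, -mean_abs))
    return np.sort(common_idx[order[:n_keep]])


def clinical_correlation(
    feature_values: pd.DataFrame, clinical_scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of consensus-feature values with symptom scores.

    Computed in patients only (callers pass patient rows). Returns a table
    with one row per (feature, score) pair: r, two-sided p and BH-FDR q over
    all pairs tested. Zero-variance vectors are skipped with a warning.
    """
    rows = []
    for feat in feature_values.columns:
        x = feature_values[feat].to_numpy(float)
        for score in clinical_scores.columns:
            s = clinical_scores[score].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(s))
            if x[ok].std() == 0 or s[ok].std() == 0:
                logger.warning("skipping zero-variance pair (%s, %s)", feat, score)
                continue
            r, p = stats.pearsonr(x[ok], s[ok])
            rows.append({"feature": feat, "score": score, "r": r, "p": p, "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
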