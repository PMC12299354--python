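"""Grid-search model selection with leakage-safe stratified cross-validation.

The search space is classifier x hyperparameters x feature-selector size
x sampler.  Five classifier families are covered: logistic regression,
k-nearest neighbors, random forest, RBF support-vector machine, and
gradient-boosted trees.  Every configuration is scored with stratified
k-fold cross-validation (default 10 folds); inside each fold the pipeline is

    impute -> relevance filter (optional) -> SMOTE (optional)
           -> ANOVA top-k selector (optional) -> standardize -> fit

with every data-dependent step fit on the training fold only.  Leaderboards
are ranked by mean macro F1 (ties: higher mean accuracy, then lexicographic
configuration id).

SMOTE is implemented here directly: each synthetic minority row is
``m + u * (nbr - m)`` for a minority row ``m``, one of its k nearest
minority neighbors ``nbr`` (Euclidean), and ``u`` uniform on [0, 1].
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autofeat import FeatureMatrix, fresh_relevance_filter
from .metrics import accuracy, confusion_matrix, macro_f1
from .metrics import welch_t_test  # noqa: F401  (re-exported: part of this module's surface)

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = (
    "logistic_regression",
    "knn",
    "random_forest",
    "svm",
    "gradient_boosted_trees",
)

#: Classifiers whose decision rule is sensitive to feature scale.
SCALE_SENSITIVE = {"logistic_regression", "knn", "svm"}

#: Default hyperparameter grid per classifier kind.
DEFAULT_HYPERPARAM_GRID: dict[str, list[dict]] = {
    "logistic_regression": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "knn": [{"n_neighbors": k} for k in (5, 11)],
    "random_forest": [{"n_estimators": 100, "max_depth": d} for d in (5, None)],
    "svm": [{"kernel": "rbf", "C": c} for c in (0.1, 1.0, 10.0)],
    "gradient_boosted_trees": [
        {"n_estimators": 100, "learning_rate": lr} for lr in (0.1, 1.0)
    ],
}

DEFAULT_SELECTOR_KS: tuple[int | None, ...] = (None, 5, 10)
DEFAULT_SAMPLERS: tuple[str, ...] = ("none", "smote")


@dataclass(frozen=True)
class ModelConfig:
    """One grid-search cell: classifier kind, hyperparameters, selector, sampler."""

    classifier_kind: str
    hyperparams: tuple[tuple[str, object], ...]   # sorted key/value pairs
    selector_k: int | None = None                 # None = all features pass
    sampler: str = "none"                         # "none" | "smote"
    seed: int = 0

    @staticmethod
    def make(classifier_kind, hyperparams: dict, selector_k=None, sampler="none", seed=0):
        if classifier_kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {classifier_kind!r}")
        if sampler not in ("none", "smote"):
            raise ValueError(f"unknown sampler {sampler!r}")
        return ModelConfig(
            classifier_kind=classifier_kind,
            hyperparams=tuple(sorted(hyperparams.items())),
            selector_k=selector_k,
            sampler=sampler,
            seed=seed,
        )

    @property
    def hyperparams_dict(self) -> dict:
        return dict(self.hyperparams)

    @property
    def config_id(self) -> str:
        hp = ",".join(f"{k}={v}" for k, v in self.hyperparams)
        sel = "none" if self.selector_k is None else str(self.selector_k)
        return f"{self.classifier_kind}({hp})|selector={sel}|sampler={self.sampler}"


@dataclass
class CVResult:
    """Cross-validated scores of one configuration."""

    fold_macro_f1: np.ndarray
    fold_accuracy: np.ndarray
    confusion: np.ndarray                 # pooled 2x2 over test folds
    error: str | None = None

    @property
    def macro_f1_mean(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    @property
    def macro_f1_sd(self) -> float:
        return float(np.std(self.fold_macro_f1, ddof=1)) if len(self.fold_macro_f1) > 1 else 0.0

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracy))


@dataclass
class RankedGrid:
    """Leaderboard: configurations ordered by mean macro F1."""

    entries: list[tuple[ModelConfig, CVResult]]
    seed: int = 0
    tie_break: str = "macro_f1_mean desc, accuracy_mean desc, config_id asc"

    def top(self, k: int = 10) -> list[tuple[ModelConfig, CVResult]]:
        return self.entries[: min(k, len(self.entries))]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank, (cfg, res) in enumerate(self.entries, start=1):
            rows.append({
                "rank": rank,
                "classifier": cfg.classifier_kind,
                "hyperparams": ",".join(f"{k}={v}" for k, v in cfg.hyperparams),
                "selector": "none" if cfg.selector_k is None else cfg.selector_k,
                "sampler": cfg.sampler,
                "macro_f1_mean": res.macro_f1_mean,
                "macro_f1_sd": res.macro_f1_sd,
                "accuracy_mean": res.accuracy_mean,
            })
        return pd.DataFrame(rows)


def default_grid(
    selector_ks=DEFAULT_SELECTOR_KS,
    samplers=DEFAULT_SAMPLERS,
    hyperparam_grid: dict[str, list[dict]] | None = None,
    seed: int = 0,
) -> list[ModelConfig]:
    """Enumerate the default grid (12 classifier settings x 3 selectors x 2 samplers)."""
    hp_grid = DEFAULT_HYPERPARAM_GRID if hyperparam_grid is None else hyperparam_grid
    configs = []
    for kind, hp_list in hp_grid.items():
        for hp, sel, smp in itertools.product(hp_list, selector_ks, samplers):
            configs.append(ModelConfig.make(kind, hp, selector_k=sel, sampler=smp, seed=seed))
    return configs


def build_classifier(config: ModelConfig, seed: int):
    """Instantiate the sklearn estimator for a configuration."""
    hp = config.hyperparams_dict
    kind = config.classifier_kind
    if kind == "logistic_regression":
        return LogisticRegression(max_iter=2000, **hp)
    if kind == "knn":
        return KNeighborsClassifier(**hp)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if kind == "svm":
        return SVC(**hp)
    if kind == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown classifier kind {kind!r}")


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (array of fold ids per sample).

    If the minority class has fewer than ``k`` members, ``k`` is reduced to
    that count with a warning.  Single-class labels are an error.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class labels: stratification is undefined")
    min_count = int(counts.min())
    if min_count < k:
        warnings.warn(
            f"minority class has {min_count} members < {k} folds; reducing k to {min_count}",
            stacklevel=2,
        )
        k = min_count
    if k < 2:
        raise ValueError("minority class too small for cross-validation (need >= 2)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold_id
    return assignment


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthesizing minority rows between nearest neighbors.

    Each synthetic row is ``m + u * (nbr - m)`` with ``m`` a random minority
    row, ``nbr`` one of its ``k_neighbors`` nearest minority neighbors
    (Euclidean; ``k_neighbors`` clipped to minority size - 1) and ``u``
    uniform on [0, 1].  Originals are preserved; output classes are equal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("cannot interpolate: minority class has fewer than 2 members")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    Xmin = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    # pairwise distances among minority rows
    d2 = np.sum((Xmin[:, None, :] - Xmin[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nbr_idx = np.argsort(d2, axis=1)[:, :k]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    m = Xmin[base]
    nbr = Xmin[nbr_idx[base, pick]]
    synthetic = m + u[:, None] * (nbr - m)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column; zero-variance columns score 0."""
    from sklearn.feature_selection import f_classif

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, _ = f_classif(X, y)
    return np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)


def select_k_best(X_train: pd.DataFrame, y_train, k: int) -> list[str]:
    """Top-k column names by ANOVA F on the training fold; ties by name."""
    if k > X_train.shape[1]:
        raise ValueError(f"k={k} exceeds {X_train.shape[1]} available columns")
    scores = _anova_f_scores(X_train.to_numpy(), np.asarray(y_train))
    order = sorted(range(X_train.shape[1]), key=lambda i: (-scores[i], X_train.columns[i]))
    return [X_train.columns[i] for i in order[:k]]


def _fit_predict_fold(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    config: ModelConfig,
    seed: int,
) -> np.ndarray:
    """Run the leakage-safe pipeline for one configuration on one fold."""
    # median imputation learned on the training fold
    medians = X_train.median()
    X_tr = X_train.fillna(medians).fillna(0.0)
    X_te = X_test.fillna(medians).fillna(0.0)
    ytr = y_train
    cols = list(X_tr.columns)
    Xtr_arr, Xte_arr = X_tr.to_numpy(), X_te.to_numpy()
    if config.sampler == "smote":
        Xtr_arr, ytr = smote_oversample(Xtr_arr, ytr, seed=seed)
    if config.selector_k is not None:
        k = min(config.selector_k, len(cols))
        X_tr_df = pd.DataFrame(Xtr_arr, columns=cols)
        chosen = select_k_best(X_tr_df, ytr, k)
        keep = [cols.index(c) for c in chosen]
        Xtr_arr = Xtr_arr[:, keep]
        Xte_arr = Xte_arr[:, keep]
    if config.classifier_kind in SCALE_SENSITIVE:
        scaler = StandardScaler().fit(Xtr_arr)
        Xtr_arr = scaler.transform(Xtr_arr)
        Xte_arr = scaler.transform(Xte_arr)
    clf = build_classifier(config, seed)
    clf.fit(Xtr_arr, ytr)
    return np.asarray(clf.predict(Xte_arr))


def cross_validate_config(
    df: pd.DataFrame,
    labels: np.ndarray,
    config: ModelConfig,
    fold_assignment: np.ndarray,
    seed: int = 0,
    fresh_cols_per_fold: list[list[str]] | None = None,
) -> CVResult:
    """Score one configuration over precomputed folds."""
    y = np.asarray(labels)
    n_folds = int(fold_assignment.max()) + 1
    f1s, accs = [], []
    pooled = np.zeros((2, 2), dtype=int)
    for fold in range(n_folds):
        test_mask = fold_assignment == fold
        X_train, X_test = df.loc[~test_mask], df.loc[test_mask]
        if fresh_cols_per_fold is not None:
            cols = fresh_cols_per_fold[fold]
            X_train, X_test = X_train[cols], X_test[cols]
        try:
            y_pred = _fit_predict_fold(X_train, y[~test_mask], X_test, config, seed + fold)
        except Exception as exc:  # scored as failure, never dropped silently
            logger.error("config %s failed on fold %d: %s", config.config_id, fold, exc)
            return CVResult(
                fold_macro_f1=np.zeros(n_folds),
                fold_accuracy=np.zeros(n_folds),
                confusion=np.zeros((2, 2), dtype=int),
                error=str(exc),
            )
        f1s.append(macro_f1(y[test_mask], y_pred))
        accs.append(accuracy(y[test_mask], y_pred))
        pooled += confusion_matrix(y[test_mask], y_pred)
    return CVResult(
        fold_macro_f1=np.array(f1s), fold_accuracy=np.array(accs), confusion=pooled
    )


def run_grid(
    matrix: FeatureMatrix | pd.DataFrame,
    labels,
    grid: list[ModelConfig] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    fresh_fdr: float | None = None,
) -> RankedGrid:
    """Evaluate every configuration with stratified CV and rank the leaderboard.

    ``fresh_fdr``, if given, applies the relevance filter per fold on the
    training split only (cached across configurations, since it depends on
    the fold, not the configuration).  A filter that retains nothing on some
    fold falls back to all columns for that fold.
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    if len(df) != len(y):
        raise ValueError("labels length does not match matrix rows")
    if grid is None:
        grid = default_grid(seed=seed)
    fold_assignment = stratified_folds(y, k=n_folds, seed=seed)
    n_actual = int(fold_assignment.max()) + 1

    fresh_cols_per_fold = None
    if fresh_fdr is not None:
        fresh_cols_per_fold = []
        for fold in range(n_actual):
            train_mask = fold_assignment != fold
            filtered, _ = fresh_relevance_filter(
                df.loc[train_mask], y[train_mask], fdr_level=fresh_fdr
            )
            cols = list(filtered.columns) if filtered.shape[1] > 0 else list(df.columns)
            fresh_cols_per_fold.append(cols)

    entries = []
    for config in grid:
        result = cross_validate_config(
            df, y, config, fold_assignment, seed=seed, fresh_cols_per_fold=fresh_cols_per_fold
        )
        entries.append((config, result))
    entries.sort(
        key=lambda e: (-e[1].macro_f1_mean, -e[1].accuracy_mean, e[0].config_id)
    )
    return RankedGrid(entries=entries, seed=seed)
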