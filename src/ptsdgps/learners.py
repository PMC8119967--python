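"""Classifier families, SMOTE rebalancing, tuning, and resampling engines.

Five lower-level classifier families are supported, mirroring the ensemble
design: a DART gradient-boosting machine (boosted trees with tree dropout),
a partial-least-squares discriminant, a lasso-regularized logistic model, an
RBF-kernel support vector machine, and a random forest standing in for the
conditional-inference forest family (flagged ``rf_fallback`` in provenance;
no permutation-test forest exists in this ecosystem).

Two resampling engines produce out-of-fold (OOF) Group-1 probabilities:

* nested leave-one-subject-out (LOSO) over day-level rows — one model per
  held-out subject, tuned on the remaining subjects only;
* stratified 10-fold, 5-times-repeated cross-validation over per-subject
  feature rows, probabilities averaged across repeats.

All preprocessing (training-mean imputation, z-scoring) and SMOTE class
rebalancing are fitted strictly inside each training split, so a held-out
subject's features and label never influence its own prediction.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import ScalingStats, impute_column_means, standardize

LEARNER_KINDS = (
    "dart_gradient_boosting",
    "pls_discriminant",
    "lasso_logistic",
    "svm_rbf",
    "conditional_forest",
)

POSITIVE_GROUP = 1  # Group 1 (PTSD) is the positive class throughout


def derive_seed(*parts) -> int:
    """Deterministic child seed (< 2^31) from arbitrary string/int parts."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) % (2**31)


@dataclass(frozen=True)
class LearnerSpec:
    """One classifier family plus its hyperparameter grid."""

    kind: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; expected one of {LEARNER_KINDS}")

    def grid_points(self) -> list[dict]:
        grid = self.grid or default_grid(self.kind)
        keys = sorted(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass(frozen=True)
class ResamplingPlan:
    """How out-of-fold predictions are produced."""

    scheme: str = "repeated_kfold"  # or "loso"
    k: int = 10
    repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("loso", "repeated_kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def default_grid(kind: str) -> dict[str, list]:
    """Moderate desk-scale tuning grids (2-4 points per family)."""
    return {
        "dart_gradient_boosting": {"max_depth": [2, 3], "rate_drop": [0.1, 0.3]},
        "pls_discriminant": {"n_components": [1, 2, 3]},
        "lasso_logistic": {"C": [0.1, 1.0, 10.0]},
        "svm_rbf": {"C": [0.5, 1.0, 4.0]},
        "conditional_forest": {"min_samples_leaf": [1, 3]},
    }[kind]


def fast_grid(kind: str) -> dict[str, list]:
    """Minimal grids (1-2 points) for full-pipeline runs."""
    return {
        "dart_gradient_boosting": {"max_depth": [2]},
        "pls_discriminant": {"n_components": [2]},
        "lasso_logistic": {"C": [1.0]},
        "svm_rbf": {"C": [1.0]},
        "conditional_forest": {"min_samples_leaf": [2]},
    }[kind]


class PLSDiscriminant(BaseEstimator, ClassifierMixin):
    """PLS regression on ±1-coded labels with logistic calibration.

    The latent PLS prediction is a continuous score; a univariate logistic
    model maps it to a Group-1 probability.
    """

    def __init__(self, n_components: int = 2, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLSDiscriminant requires exactly two classes")
        target = np.where(y == self.classes_[1], 1.0, -1.0)
        ncomp = int(min(self.n_components, X.shape[1], max(1, X.shape[0] - 1)))
        self.pls_ = PLSRegression(n_components=ncomp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pls_.fit(X, target)
        score = self.pls_.predict(X).ravel().reshape(-1, 1)
        self.calibrator_ = LogisticRegression()
        self.calibrator_.fit(score, (target > 0).astype(int))
        return self

    def predict_proba(self, X):
        score = self.pls_.predict(np.asarray(X, dtype=float)).ravel().reshape(-1, 1)
        return self.calibrator_.predict_proba(score)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


def make_estimator(kind: str, params: dict, seed: int):
    """Instantiate one classifier of the given family with grid params applied."""
    if kind == "dart_gradient_boosting":
        base = dict(
            booster="dart",
            n_estimators=40,
            max_depth=2,
            learning_rate=0.3,
            rate_drop=0.1,
            skip_drop=0.25,
            subsample=0.9,
            tree_method="hist",
            eval_metric="logloss",
            n_jobs=1,
            verbosity=0,
            random_state=seed,
        )
        base.update(params)
        return XGBClassifier(**base)
    if kind == "pls_discriminant":
        return PLSDiscriminant(seed=seed, **params)
    if kind == "lasso_logistic":
        base = dict(l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=2000, random_state=seed)
        base.update(params)
        return LogisticRegression(**base)
    if kind == "svm_rbf":
        base = dict(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        base.update(params)
        # Platt-scaled decision scores; internal CV is deterministic (no shuffle)
        return CalibratedClassifierCV(SVC(**base), method="sigmoid", cv=3, ensemble=False)
    if kind == "conditional_forest":
        # rf_fallback: permutation-test split selection is unavailable here
        base = dict(n_estimators=100, max_features="sqrt", n_jobs=1, random_state=seed)
        base.update(params)
        return RandomForestClassifier(**base)
    raise ValueError(f"unknown learner kind {kind!r}")


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: synthesize minority rows as convex combinations of minority k-NN.

    Each synthetic point is x_i + u * (x_nn - x_i), u ~ Uniform(0, 1), where
    x_nn is one of x_i's ``k_neighbors`` nearest minority neighbors
    (Euclidean). Majority rows pass through unchanged. ``target_ratio`` is
    the desired minority/majority count ratio (1.0 = full balance);
    ``k_neighbors`` shrinks automatically when the minority is small.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE needs both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority examples")
    n_target = int(round(target_ratio * n_maj))
    n_new = max(0, n_target - n_min)
    if n_new == 0:
        return X.copy(), y.copy()

    X_min = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neigh = idx[base, pick]
    synthetic = X_min[base] + u[:, None] * (X_min[neigh] - X_min[base])
    X_aug = np.vstack([X, synthetic])
    y_aug = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_aug, y_aug


@dataclass
class FoldModel:
    """A fitted learner bundled with its training-split preprocessing stats."""

    stats: ScalingStats
    estimator: object
    chosen_params: dict
    positive_index: int

    def predict_group1_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = standardize(impute_column_means(X, self.stats), self.stats)
        return self.estimator.predict_proba(Z.to_numpy())[:, self.positive_index]


def _fit_once(kind, params, X_train, y01, seed, smote_k, smote_ratio) -> FoldModel:
    stats = ScalingStats.fit(X_train)
    Z = standardize(impute_column_means(X_train, stats), stats)
    rng = np.random.default_rng(derive_seed(seed, "smote"))
    Za, ya = smote_oversample(Z.to_numpy(), y01, k_neighbors=smote_k, target_ratio=smote_ratio, rng=rng)
    est = make_estimator(kind, params, seed=derive_seed(seed, "est"))
    est.fit(Za, ya)
    positive_index = int(np.flatnonzero(est.classes_ == 1)[0])
    return FoldModel(stats=stats, estimator=est, chosen_params=params, positive_index=positive_index)


def tune_and_fit(
    spec: LearnerSpec,
    X: pd.DataFrame,
    y01: np.ndarray,
    inner_k: int = 3,
    groups: np.ndarray | None = None,
    smote_k: int = 5,
    smote_ratio: float = 1.0,
    seed: int | None = None,
) -> FoldModel:
    """Grid-tune by inner-CV ROC-AUC, then refit the winner on all data.

    Every grid point is scored by out-of-fold AUC in an inner ``inner_k``-fold
    split (grouped by subject when day-level ``groups`` are given, else
    stratified by class); SMOTE and preprocessing are refitted inside every
    inner training split. Single-point grids skip the inner loop.
    """
    seed = spec.seed if seed is None else seed
    points = spec.grid_points()
    if len(np.unique(y01)) < 2:
        raise ValueError("tune_and_fit needs both classes in the training labels")
    best = points[0]
    if len(points) > 1:
        if groups is not None:
            splitter = GroupKFold(n_splits=min(inner_k, len(np.unique(groups))))
            splits = list(splitter.split(X, y01, groups))
        else:
            splitter = StratifiedKFold(
                n_splits=inner_k, shuffle=True, random_state=derive_seed(seed, "inner")
            )
            splits = list(splitter.split(X, y01))
        scores = []
        for params in points:
            fold_aucs = []
            for fi, (tr, te) in enumerate(splits):
                y_tr, y_te = y01[tr], y01[te]
                if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                    continue  # degenerate fold: AUC undefined
                model = _fit_once(
                    spec.kind, params, X.iloc[tr], y_tr,
                    derive_seed(seed, "tune", fi), smote_k, smote_ratio,
                )
                fold_aucs.append(roc_auc_score(y_te, model.predict_group1_proba(X.iloc[te])))
            if not fold_aucs:
                raise ValueError("all inner folds degenerate; cannot tune")
            scores.append(np.mean(fold_aucs))
        best = points[int(np.argmax(scores))]
    return _fit_once(spec.kind, best, X, y01, derive_seed(seed, "final"), smote_k, smote_ratio)


def cross_validated_probabilities(
    spec: LearnerSpec,
    X: pd.DataFrame,
    labels: pd.Series,
    plan: ResamplingPlan,
    smote_k: int = 5,
    smote_ratio: float = 1.0,
    inner_k: int = 3,
    arm: str = "",
) -> pd.DataFrame:
    """Repeated stratified k-fold OOF Group-1 probabilities, one per subject.

    ``X`` is indexed by subject_id; ``labels`` gives group membership (1/2)
    per subject. Within each repeat every subject is held out exactly once;
    per-subject probabilities are averaged over repeats. Fold assignment is a
    deterministic function of (plan.seed, repeat, subject ids, labels).
    """
    if plan.scheme != "repeated_kfold":
        raise ValueError("cross_validated_probabilities requires a repeated_kfold plan")
    labels = labels.loc[X.index]
    y01 = (labels.to_numpy() == POSITIVE_GROUP).astype(int)
    if len(X) < plan.k:
        raise ValueError(f"fewer subjects ({len(X)}) than folds ({plan.k})")
    probs = np.zeros(len(X))
    for rep in range(plan.repeats):
        rep_seed = derive_seed(plan.seed, "rep", rep)
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=rep_seed)
        for fi, (tr, te) in enumerate(splitter.split(X, y01)):
            model = tune_and_fit(
                spec, X.iloc[tr], y01[tr], inner_k=inner_k,
                smote_k=smote_k, smote_ratio=smote_ratio,
                seed=derive_seed(spec.seed, plan.seed, rep, fi),
            )
            probs[te] += model.predict_group1_proba(X.iloc[te])
    probs /= plan.repeats
    return pd.DataFrame(
        {
            "subject_id": X.index,
            "prob_group1": probs,
            "arm": arm,
            "learner": spec.kind,
        }
    )


def nested_loso_probabilities(
    stacked_features: pd.DataFrame,
    labels: pd.DataFrame,
    spec: LearnerSpec,
    feature_cols: tuple[str, ...] = ("dma_minutes", "mdr_km"),
    inner_k: int = 5,
    smote_k: int = 5,
    smote_ratio: float = 1.0,
) -> pd.DataFrame:
    """Nested leave-one-subject-out day-level probabilities.

    One model per held-out subject, trained and grid-tuned (inner CV grouped
    by subject) on every other subject's day rows only; predicts a Group-1
    probability for each of the held-out subject's 3–7 days. The held-out
    subject's rows and label never enter training, tuning, preprocessing or
    SMOTE for its own model.
    """
    label_map = labels.set_index("subject_id")["group"]
    subjects = list(label_map.index)
    if len(subjects) < 3:
        raise ValueError("nested LOSO needs at least 3 subjects")
    counts = stacked_features["subject_id"].value_counts()
    missing = [s for s in subjects if counts.get(s, 0) == 0]
    if missing:
        raise ValueError(f"subjects without any day rows: {missing[:5]}")

    X_all = stacked_features[list(feature_cols)]
    out = []
    for sid in subjects:
        held = stacked_features["subject_id"] == sid
        X_tr = X_all[~held]
        groups_tr = stacked_features.loc[~held, "subject_id"].to_numpy()
        y_tr = (label_map.loc[groups_tr].to_numpy() == POSITIVE_GROUP).astype(int)
        model = tune_and_fit(
            spec, X_tr, y_tr, inner_k=inner_k, groups=groups_tr,
            smote_k=smote_k, smote_ratio=smote_ratio,
            seed=derive_seed(spec.seed, "loso", sid),
        )
        p = model.predict_group1_proba(X_all[held])
        day_rows = stacked_features.loc[held, ["subject_id", "day_index"]].copy()
        day_rows["prob_group1"] = p
        out.append(day_rows)
    return pd.concat(out, ignore_index=True)
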