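"""Unimodal and fusion classifier training and evaluation.

Implements the two evaluation protocols used throughout the analysis:
a single matched-train / held-out-test split with inner grid-search
tuning, and repeated stratified k-fold cross-validation (default 50
repeats of 5 folds, stratified on diagnosis x sex) whose per-fold AUC
vectors support paired Wilcoxon model comparisons. Multimodal models
are concatenation fusions of per-block z-scored feature tables.
Feature attribution uses a sampled-permutation Shapley estimate against
a training-mean baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .audit import _auc_rank

__all__ = ["Dataset", "ModelSpec", "EvalProtocol", "MetricSet", "ImportanceResult",
           "fit_eval_holdout", "repeated_cv_eval", "fuse_blocks",
           "compare_fold_aucs", "shapley_importance", "DEFAULT_GRIDS"]

DEFAULT_GRIDS = {
    "logistic": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"model__kernel": ["linear", "rbf"], "model__C": [0.1, 1.0, 10.0],
            "model__gamma": ["scale"]},
    "random_forest": {"model__n_estimators": [200, 500], "model__max_depth": [None, 8]},
}


@dataclass
class Dataset:
    """Samples x features table with labels, sex and subject identity."""

    X: pd.DataFrame
    y: np.ndarray                  # 0/1, 1 = case
    sex: np.ndarray                # 'F'/'M'
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.dtype.kind not in "biu":
            self.y = (self.y == "case").astype(int)
        self.sex = np.asarray(self.sex)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.sex) == len(self.subject_ids) == n):
            raise ValueError("inconsistent dataset dimensions")


@dataclass
class ModelSpec:
    family: str = "logistic"
    grid: Optional[dict] = None
    random_state: int = 0

    def estimator(self):
        if self.family == "logistic":
            est = LogisticRegression(max_iter=5000)
        elif self.family == "svm":
            est = SVC(probability=False, random_state=self.random_state)
        elif self.family == "random_forest":
            est = RandomForestClassifier(random_state=self.random_state)
        else:
            raise ValueError(f"unknown model family {self.family!r}")
        return Pipeline([("scale", StandardScaler()), ("model", est)])

    def param_grid(self) -> dict:
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        if not grid:
            raise ValueError("hyperparameter grid must be non-empty")
        return grid


@dataclass
class EvalProtocol:
    mode: str = "repeated_cv"          # or "holdout"
    n_repeats: int = 50
    k: int = 5
    inner_k: int = 3
    seed: int = 0


@dataclass
class MetricSet:
    auc: float
    sensitivity: float
    specificity: float
    accuracy_female: float
    accuracy_male: float
    per_fold: Optional[pd.DataFrame] = None

    def as_dict(self) -> dict:
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy_female": self.accuracy_female,
                "accuracy_male": self.accuracy_male}


@dataclass
class ImportanceResult:
    values: pd.DataFrame           # test predictions x features, signed Shapley values
    base_value: float
    mean_abs: pd.Series            # descending mean |Shapley| per feature


def _scores_and_labels(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(continuous score, hard 0/1 prediction at the fixed threshold)."""
    if hasattr(model, "predict_proba"):
        s = model.predict_proba(X)[:, 1]
        hard = (s >= 0.5).astype(int)
    else:
        s = model.decision_function(X)
        hard = (s >= 0.0).astype(int)
    return s, hard


def _metrics(scores, hard, y, sex) -> dict:
    y = np.asarray(y)
    pos, neg = y == 1, y == 0
    sens = float((hard[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((hard[neg] == 0).mean()) if neg.any() else np.nan
    f, m = sex == "F", sex == "M"
    acc_f = float((hard[f] == y[f]).mean()) if f.any() else np.nan
    acc_m = float((hard[m] == y[m]).mean()) if m.any() else np.nan
    return {"auc": _auc_rank(scores, y), "sensitivity": sens, "specificity": spec,
            "accuracy_female": acc_f, "accuracy_male": acc_m}


def _tune_and_fit(Xtr, ytr, spec: ModelSpec, inner_k: int, seed: int):
    grid = spec.param_grid()
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    pipe = spec.estimator()
    if n_combos == 1:
        pipe.set_params(**{k: v[0] for k, v in grid.items()})
        pipe.fit(Xtr, ytr)
        return pipe
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=inner, scoring="roc_auc", n_jobs=1, refit=True)
    search.fit(Xtr, ytr)
    return search.best_estimator_


def fit_eval_holdout(
    train: Dataset,
    test: Dataset,
    spec: ModelSpec,
    features: Optional[Sequence] = None,
    inner_k: int = 3,
    seed: int = 0,
) -> MetricSet:
    """Tune on the training set (nested stratified CV), refit, evaluate once."""
    overlap = set(train.subject_ids) & set(test.subject_ids)
    if overlap:
        raise ValueError(f"subject-id leakage between train and test: {sorted(overlap)[:5]}")
    feats = list(features) if features is not None else list(train.X.columns)
    missing = [f for f in feats if f not in test.X.columns]
    if missing:
        raise ValueError(f"features absent from test set: {missing[:5]}")
    Xtr = train.X[feats].to_numpy(dtype=float)
    Xte = test.X[feats].to_numpy(dtype=float)
    model = _tune_and_fit(Xtr, train.y, spec, inner_k, seed)
    s, hard = _scores_and_labels(model, Xte)
    return MetricSet(**_metrics(s, hard, test.y, test.sex))


def _joint_strata(y: np.ndarray, sex: np.ndarray) -> np.ndarray:
    return np.char.add(np.asarray(y).astype(str), np.asarray(sex).astype(str))


def repeated_cv_eval(
    data: Dataset,
    spec: ModelSpec,
    protocol: EvalProtocol | None = None,
) -> MetricSet:
    """Repeated stratified k-fold CV with inner grid-search tuning.

    Outer folds stratify on the joint diagnosis x sex label; the summary
    is the unweighted mean over all n_repeats * k outer test folds, and
    the per-fold AUC vector is retained for paired comparisons.
    """
    proto = protocol or EvalProtocol()
    strata = _joint_strata(data.y, data.sex)
    counts = pd.Series(strata).value_counts()
    if (counts < proto.k).any():
        small = counts[counts < proto.k].index.tolist()
        raise ValueError(f"stratum/strata {small} smaller than k={proto.k}")
    X = data.X.to_numpy(dtype=float)
    records = []
    for rep in range(proto.n_repeats):
        outer = StratifiedKFold(n_splits=proto.k, shuffle=True,
                                random_state=proto.seed + rep)
        for fold, (tr, te) in enumerate(outer.split(X, strata)):
            model = _tune_and_fit(X[tr], data.y[tr], spec, proto.inner_k,
                                  seed=proto.seed + rep)
            s, hard = _scores_and_labels(model, X[te])
            rec = _metrics(s, hard, data.y[te], data.sex[te])
            rec.update({"repeat": rep, "fold": fold})
            records.append(rec)
    per_fold = pd.DataFrame(records)
    means = per_fold[["auc", "sensitivity", "specificity",
                      "accuracy_female", "accuracy_male"]].mean()
    return MetricSet(auc=float(means["auc"]), sensitivity=float(means["sensitivity"]),
                     specificity=float(means["specificity"]),
                     accuracy_female=float(means["accuracy_female"]),
                     accuracy_male=float(means["accuracy_male"]),
                     per_fold=per_fold)


def fuse_blocks(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate feature blocks (samples x features) sharing a sample index.

    Column names are prefixed by block name; scaling is left to the model
    pipeline so that z-scoring parameters come from training folds only.
    """
    names = list(blocks)
    first = blocks[names[0]].index
    for n in names[1:]:
        if set(blocks[n].index) != set(first):
            raise ValueError(f"sample ids of block {n!r} do not match")
    parts = []
    for n in names:
        b = blocks[n].loc[first]
        b = b.rename(columns={c: f"{n}__{c}" for c in b.columns})
        parts.append(b)
    return pd.concat(parts, axis=1)


def compare_fold_aucs(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired per-fold AUCs.

    Zero differences are dropped (standard convention); if every pair is
    tied the p-value is reported as 1.0.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired AUC vectors must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    stat, p = wilcoxon(a, b)
    return float(stat), float(p)


def shapley_importance(
    model,
    test_X: pd.DataFrame,
    baseline: pd.Series | np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Sampled-permutation Shapley attribution of model scores.

    For each test sample, features are walked from the baseline (training
    feature means) to the sample's values in random orders; the marginal
    change in model score at each insertion, averaged over orders, is the
    feature's Shapley value. Importance = mean |value| over predictions.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if hasattr(model, "predict_proba"):
        score = lambda Z: model.predict_proba(Z)[:, 1]
    else:
        score = model.decision_function
    base = np.asarray(baseline, dtype=float)
    Xte = test_X.to_numpy(dtype=float)
    n, d = Xte.shape
    rng = np.random.default_rng(seed)
    base_value = float(score(base[None, :])[0])

    values = np.zeros((n, d))
    for i in range(n):
        x = Xte[i]
        acc = np.zeros(d)
        for _ in range(n_permutations):
            perm = rng.permutation(d)
            # batch evaluation of the d+1 points along one insertion path
            path = np.tile(base, (d + 1, 1))
            current = base.copy()
            for step, j in enumerate(perm, start=1):
                current[j] = x[j]
                path[step] = current
            s = score(path)
            acc[perm] += np.diff(s)
        values[i] = acc / n_permutations
    frame = pd.DataFrame(values, index=test_X.index, columns=test_X.columns)
    mean_abs = frame.abs().mean(axis=0).sort_values(ascending=False)
    return ImportanceResult(values=frame, base_value=base_value, mean_abs=mean_abs)
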