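"""Two-step ensemble mRMR feature selection.

Step one builds 50 mRMR rank lists of the top 500 features, each from a
stratified 80% subsample of subjects (stratified on diagnosis x sex);
every feature receives a placement score per list (top = L, bottom = 1,
absent = 0) and the mean score across lists gives a single consensus
ranking. Step two scans nested head subsets of the consensus ranking
(50, 60, ..., 500 features), scores each on a held-out set, and selects
the best subset with 200 or fewer features (ties -> fewest features).

The mRMR variant is FCQ: F-statistic relevance against the binary label
divided by mean absolute Pearson correlation with the already-selected
features (quotient scheme; difference scheme optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .audit import _auc_rank

__all__ = ["MRMRConfig", "FeatureRanking", "ScanResult", "mrmr_rank",
           "ensemble_rank", "scan_feature_counts", "select_best_subset"]

_REDUNDANCY_FLOOR = 1e-6


@dataclass
class MRMRConfig:
    list_length: int = 500
    scheme: str = "quotient"          # or "difference"

    def __post_init__(self) -> None:
        if self.scheme not in ("quotient", "difference"):
            raise ValueError(f"unknown mRMR scheme {self.scheme!r}")


@dataclass
class FeatureRanking:
    scores: pd.Series                 # mean rank score per feature, descending
    per_repeat_lists: list[list]

    @property
    def order(self) -> list:
        return list(self.scores.index)


@dataclass
class ScanResult:
    grid: list[int]
    aucs: pd.DataFrame                # rows = counts, columns = classifier names
    ranking: FeatureRanking


def _f_relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each feature against the binary label."""
    g1, g0 = X[y == 1], X[y == 0]
    n1, n0 = g1.shape[0], g0.shape[0]
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    grand = X.mean(axis=0)
    ss_between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ss_within = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    df_w = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def mrmr_rank(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: MRMRConfig | None = None,
) -> list:
    """Greedy mRMR ordering of features (features x samples input).

    First pick maximizes relevance; each subsequent pick maximizes
    relevance / mean |Pearson r| with the selected set (redundancy floored
    at 1e-6). Ties broken by feature-id lexical order. Constant features
    have zero relevance and are never preferred over informative ones.
    """
    cfg = config or MRMRConfig()
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "case").astype(int)
    X = matrix.to_numpy(dtype=float).T                 # samples x features
    ids = list(matrix.index)
    d = X.shape[1]
    if d < 2:
        raise ValueError("mRMR needs at least 2 features")
    rel = _f_relevance(X, y)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")
    L = min(cfg.list_length, d)

    # standardized columns for incremental correlation updates
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    constant = sd == 0

    lex_rank = np.empty(d, dtype=int)  # lexical tie-break key
    lex_rank[np.argsort(np.array(ids, dtype=object))] = np.arange(d)

    selected: list[int] = []
    red_sum = np.zeros(d)
    remaining = np.ones(d, dtype=bool)
    n = X.shape[0]
    for step in range(L):
        if step == 0:
            crit = rel.copy()
        else:
            red = red_sum / len(selected)
            red = np.maximum(red, _REDUNDANCY_FLOOR)
            if cfg.scheme == "quotient":
                crit = rel / red
            else:
                crit = rel - red
        crit = np.where(remaining, crit, -np.inf)
        best = np.lexsort((lex_rank, -crit))[0]
        selected.append(best)
        remaining[best] = False
        # update redundancy sums with |corr| to the newly selected feature
        r_new = np.abs(Z.T @ Z[:, best] / n)
        r_new[constant] = 0.0
        if constant[best]:
            r_new[:] = 0.0
        red_sum += r_new
    return [ids[i] for i in selected]


def _stratified_subsample(strata: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    idx = []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        if members.size < 2:
            raise ValueError(f"stratum {s!r} too small to subsample")
        k = max(1, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def ensemble_rank(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    n_repeats: int = 50,
    subsample: float = 0.8,
    config: MRMRConfig | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Ensemble mRMR over stratified subsamples.

    A feature at position p of a length-L list scores L+1-p; a feature
    absent from a list scores 0 for that list. The final score is the
    mean over all lists; the consensus order is descending score with
    lexical tie-break.
    """
    cfg = config or MRMRConfig()
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "case").astype(int)
    strata = np.char.add(y.astype(str), np.asarray(sex).astype(str))
    rng = np.random.default_rng(seed)
    ids = list(matrix.index)
    totals = pd.Series(0.0, index=ids)
    lists: list[list] = []
    for _ in range(n_repeats):
        if subsample >= 1.0:
            cols = np.arange(matrix.shape[1])
        else:
            cols = _stratified_subsample(strata, subsample, rng)
        sub = matrix.iloc[:, cols]
        ordered = mrmr_rank(sub, y[cols], cfg)
        lists.append(ordered)
        L = len(ordered)
        for p, f in enumerate(ordered, start=1):
            totals[f] += L + 1 - p
    scores = totals / n_repeats
    scores = scores.sort_index().sort_values(ascending=False, kind="stable")
    return FeatureRanking(scores=scores, per_repeat_lists=lists)


def scan_feature_counts(
    train: pd.DataFrame,
    train_labels,
    holdout: pd.DataFrame,
    holdout_labels,
    ranking: FeatureRanking,
    grid: Sequence[int] | None = None,
    classifiers: Optional[dict] = None,
    train_subjects: Optional[Sequence] = None,
    holdout_subjects: Optional[Sequence] = None,
) -> ScanResult:
    """Evaluate nested head subsets of the consensus ranking on a holdout.

    Matrices are features x samples. Standardization and model fitting use
    the training set only. If subject ids are given for both sets they
    must be disjoint (leakage guard).
    """
    if train_subjects is not None and holdout_subjects is not None:
        overlap = set(train_subjects) & set(holdout_subjects)
        if overlap:
            raise ValueError(f"subject-id leakage between train and holdout: {sorted(overlap)[:5]}")
    if grid is None:
        grid = list(range(50, 501, 10))
    grid = sorted(set(int(c) for c in grid))
    if classifiers is None:
        classifiers = {"logistic": LogisticRegression(max_iter=2000)}
    y_tr = np.asarray(train_labels)
    y_ho = np.asarray(holdout_labels)
    if y_tr.dtype.kind not in "biu":
        y_tr = (y_tr == "case").astype(int)
    if y_ho.dtype.kind not in "biu":
        y_ho = (y_ho == "case").astype(int)

    order = [f for f in ranking.order if f in train.index]
    rows = {}
    for c in grid:
        feats = order[:c]
        Xtr = train.loc[feats].to_numpy(dtype=float).T
        Xho = holdout.loc[feats].to_numpy(dtype=float).T
        rows[c] = {}
        for name, est in classifiers.items():
            pipe = make_pipeline(StandardScaler(), clone(est))
            pipe.fit(Xtr, y_tr)
            if hasattr(pipe, "predict_proba"):
                s = pipe.predict_proba(Xho)[:, 1]
            else:
                s = pipe.decision_function(Xho)
            rows[c][name] = _auc_rank(s, y_ho)
    aucs = pd.DataFrame(rows).T
    aucs.index.name = "n_features"
    return ScanResult(grid=list(grid), aucs=aucs, ranking=ranking)


def select_best_subset(
    scan: ScanResult,
    max_features: int = 200,
) -> dict:
    """Best subset with <= max_features per classifier; AUC ties -> fewest features."""
    eligible = [c for c in scan.grid if c <= max_features]
    if not eligible:
        raise ValueError(f"no grid point at or below {max_features} features")
    out = {}
    for name in scan.aucs.columns:
        col = scan.aucs.loc[eligible, name]
        best_auc = col.max()
        best_count = min(c for c in eligible if col[c] == best_auc)
        out[name] = {
            "n_features": int(best_count),
            "auc": float(best_auc),
            "features": scan.ranking.order[:best_count],
        }
    return out
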