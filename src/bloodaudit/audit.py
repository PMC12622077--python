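"""Random-gene-set bias audit.

An unbiased case/control expression matrix should give near-chance
classification from randomly chosen gene sets. The audit samples many
gene sets at random (default 10,000 sets of 75 features), trains an
L2-regularized logistic regression under leave-one-out cross-validation
on each, and scores the pooled out-of-fold predictions by rank-based
AUC. The mean of the resulting AUC distribution measures dataset-level
systematic bias; paired comparisons between adjustment variants (same
gene-set manifest replayed on each) quantify how much bias an
adjustment step removed.

Also provides the technical-replicate concordance diagnostic: mean
within-replicate sample correlation versus mean between-subject
correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from ._logistic import decision_values, fit_logistic

__all__ = [
    "AuditConfig", "AuditResult", "AuditComparison",
    "sample_gene_sets", "loocv_auc", "run_audit", "compare_audits",
    "replicate_concordance",
]


@dataclass
class AuditConfig:
    """Audit protocol: defaults mirror the published sampling-at-random setup."""

    n_iterations: int = 10000
    set_size: int = 75
    classifier: str = "logistic"
    seed: int = 0
    shared_set_manifest: Optional[list] = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class AuditResult:
    aucs: np.ndarray
    manifest: list            # feature ids per iteration
    config: AuditConfig

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if self.aucs.size > 1 else 0.0

    def summary(self) -> str:
        return f"{self.mean:.3f}±{self.sd:.2f} AUC over {self.aucs.size} iterations"

    def to_json(self, path) -> None:
        payload = {
            "aucs": self.aucs.tolist(),
            "mean": self.mean, "sd": self.sd,
            "manifest": [list(s) for s in self.manifest],
            "config": {"n_iterations": self.config.n_iterations,
                       "set_size": self.config.set_size,
                       "classifier": self.config.classifier,
                       "seed": self.config.seed},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class AuditComparison:
    statistic: float
    pvalue: float
    mean_diff: float          # mean(a) - mean(b)
    paired: bool


def sample_gene_sets(
    feature_ids: Sequence,
    set_size: int,
    n_iterations: int,
    seed: int,
) -> list[list]:
    """Uniform without-replacement gene sets, independent across iterations."""
    ids = list(feature_ids)
    if set_size > len(ids):
        raise ValueError(f"set_size {set_size} exceeds feature universe {len(ids)}")
    rng = np.random.default_rng(seed)
    return [[ids[j] for j in rng.choice(len(ids), size=set_size, replace=False)]
            for _ in range(n_iterations)]


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def loocv_auc(
    matrix_subset: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    classifier: str = "logistic",
    C: float = 1.0,
) -> float:
    """Leave-one-out CV AUC of a logistic model on one feature subset.

    ``matrix_subset`` is features x samples. Each fold standardizes
    features on its n-1 training samples, fits the penalized logistic
    model (warm-started from the full-data fit) and scores the held-out
    sample; the single AUC is computed on the pooled out-of-fold scores.
    """
    if classifier != "logistic":
        raise ValueError(f"unknown audit classifier {classifier!r}")
    X = np.asarray(matrix_subset, dtype=float).T      # samples x features
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    # full-data fit for warm starts (standardized on all samples)
    mu_all, sd_all = X.mean(axis=0), X.std(axis=0)
    sd_all[sd_all == 0] = 1.0
    theta_full = fit_logistic((X - mu_all) / sd_all, y, C=C)

    s1 = X.sum(axis=0)
    s2 = (X ** 2).sum(axis=0)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        mu = (s1 - X[i]) / (n - 1)
        var = (s2 - X[i] ** 2) / (n - 1) - mu ** 2
        sd = np.sqrt(np.clip(var, 0.0, None))
        sd[sd == 0] = 1.0
        Xt = (X[mask] - mu) / sd
        theta = fit_logistic(Xt, y[mask], C=C, w0=theta_full)
        scores[i] = decision_values(((X[i] - mu) / sd)[None, :], theta)[0]
        mask[i] = True
    return _auc_rank(scores, y)


def run_audit(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: AuditConfig,
) -> AuditResult:
    """Run the sampling-at-random audit on one dataset variant."""
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "case").astype(int)
    if config.shared_set_manifest is not None:
        manifest = [list(s) for s in config.shared_set_manifest]
        missing = {g for s in manifest for g in s} - set(matrix.index)
        if missing:
            raise ValueError(f"manifest features absent from matrix: {sorted(missing)[:5]}")
    else:
        manifest = sample_gene_sets(list(matrix.index), config.set_size,
                                    config.n_iterations, config.seed)
    aucs = np.empty(len(manifest))
    values = matrix.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(matrix.index)}
    for k, gene_set in enumerate(manifest):
        rows = [pos[g] for g in gene_set]
        aucs[k] = loocv_auc(values[rows], y, classifier=config.classifier)
    return AuditResult(aucs=aucs, manifest=manifest, config=config)


def compare_audits(a: AuditResult, b: AuditResult) -> AuditComparison:
    """Paired Wilcoxon when the two audits share a gene-set manifest,
    two-sided rank-sum otherwise."""
    if a.aucs.size == 0 or b.aucs.size == 0:
        raise ValueError("empty audit result")
    same_manifest = a.manifest == b.manifest
    mean_diff = a.mean - b.mean
    if same_manifest:
        if a.aucs.size != b.aucs.size:
            raise ValueError("paired comparison requires equal iteration counts")
        diffs = a.aucs - b.aucs
        if np.all(diffs == 0):
            return AuditComparison(0.0, 1.0, 0.0, True)
        stat, p = wilcoxon(a.aucs, b.aucs)
        return AuditComparison(float(stat), float(p), mean_diff, True)
    stat, p = mannwhitneyu(a.aucs, b.aucs, alternative="two-sided")
    return AuditComparison(float(stat), float(p), mean_diff, False)


def replicate_concordance(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "replicate_group",
) -> tuple[float, float]:
    """(mean within-replicate r, mean between-sample r) across all sample pairs."""
    groups = metadata.loc[matrix.columns, group_col]
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("no replicate groups of size >= 2")
    corr = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    n = corr.shape[0]
    g = groups.to_numpy()
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if g[i] == g[j] else between).append(corr[i, j])
    return float(np.mean(within)), float(np.mean(between))
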