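"""White-blood-cell deconvolution by non-negative least squares.

Estimates per-sample cell-type mixture proportions from bulk log2
expression against a linear-scale signature matrix: for each sample m,
solve min ||S w - m||_2 s.t. w >= 0 over the signature genes, report
fractions w / sum(w), the absolute immune signal sum(w), and z-scored
per-cell-type covariates (population sd) for downstream adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .synthetic import SignatureMatrix

__all__ = ["CellFractionEstimates", "estimate_fractions", "scale_covariate",
           "covariate_pc_association"]


@dataclass
class CellFractionEstimates:
    fractions: pd.DataFrame       # samples x cell types, rows sum to 1
    absolute_score: pd.Series     # per-sample sum of unnormalized coefficients
    scaled_covariates: pd.DataFrame  # z-scored fraction per cell type

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("cell fractions must sum to 1 per sample")
        if (self.absolute_score < 0).any():
            raise ValueError("absolute_score must be non-negative")


def _unlog(expr: pd.DataFrame, convention: str) -> pd.DataFrame:
    if convention == "log2p1":
        return np.exp2(expr) - 1.0
    if convention == "log2":
        return np.exp2(expr)
    raise ValueError(f"unknown log convention {convention!r}")


def estimate_fractions(
    expr: pd.DataFrame,
    signature: SignatureMatrix,
    log_convention: str = "log2p1",
) -> CellFractionEstimates:
    """NNLS mixture estimate per sample, restricted to signature genes.

    ``log_convention`` controls how log2 expression is returned to the
    linear scale: ``"log2p1"`` inverts log2(x+1) (the generator's
    convention), ``"log2"`` inverts a plain log2.
    """
    missing = [g for g in signature.gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing[:5]}")
    linear = _unlog(expr.loc[signature.gene_ids], log_convention).to_numpy()
    linear = np.clip(linear, 0.0, None)
    S = signature.values

    n_samples = linear.shape[1]
    W = np.empty((n_samples, S.shape[1]))
    for j in range(n_samples):
        w, _ = nnls(S, linear[:, j])
        W[j] = w
    totals = W.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = expr.columns[zero][0]
        raise ValueError(f"degenerate sample {bad!r}: all mixture coefficients zero")

    fractions = pd.DataFrame(W / totals[:, None], index=expr.columns,
                             columns=signature.cell_type_names)
    absolute = pd.Series(totals, index=expr.columns, name="absolute_score")
    mu = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=0)
    scaled = (fractions - mu) / sd.replace(0.0, np.nan)
    return CellFractionEstimates(fractions, absolute, scaled)


def scale_covariate(estimates: CellFractionEstimates, cell_type: str) -> pd.Series:
    """z-score (population sd) of one cell type's fraction vector."""
    if cell_type not in estimates.fractions.columns:
        raise KeyError(f"cell type {cell_type!r} not present")
    v = estimates.fractions[cell_type]
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError(f"fraction vector for {cell_type!r} has zero variance")
    return (v - v.mean()) / sd


def covariate_pc_association(
    expr: pd.DataFrame,
    covariate: np.ndarray | pd.Series,
    n_components: int,
) -> pd.DataFrame:
    """Pearson association of a covariate with leading expression PCs.

    PCA on gene-centered data; sample scores of the first ``n_components``
    components are correlated with the covariate. Components are reported
    in their raw orientation (the sign of a PC is arbitrary) alongside |r|.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != expr.shape[1]:
        raise ValueError("covariate length must equal sample count")
    if n_components > min(expr.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
    # samples as observations: SVD of centered genes x samples
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    rows = []
    for k in range(n_components):
        scores = vt[k]
        r, p = pearsonr(cov, scores)
        rows.append({"component": k + 1, "r": r, "abs_r": abs(r), "p": p})
    return pd.DataFrame(rows).set_index("component")
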