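"""Supervised batch and covariate adjustment for expression matrices.

Implements the classic parametric empirical-Bayes location/scale batch
model: per gene g, batch b, sample i in batch b,

    x_gib = alpha_g + X_i beta_g + gamma_gb + delta_gb * eps_gib

with a normal prior on the batch locations gamma_gb and an inverse-gamma
prior on the batch scales delta^2_gb, hyperparameters estimated by method
of moments across genes, and the posterior solved by the standard fixed
point iteration. The preserved design (diagnosis, and any covariates to
keep) is estimated jointly and re-injected after correction, so the
adjustment is "supervised": it never absorbs the class effect into a
batch term.

A second, continuous-covariate step residualizes each gene on a scalar
covariate (e.g. the scaled neutrophil estimate) while retaining the
diagnosis effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdjustmentModel", "fit_eb_batch_model", "apply_adjustment",
           "adjust_stepwise", "residualize_continuous"]


@dataclass
class AdjustmentModel:
    """Fitted empirical-Bayes batch model for one batch variable."""

    feature_ids: list
    batch_levels: list
    batch_of_sample: np.ndarray       # integer batch index per sample
    alpha: np.ndarray                 # per-gene grand intercept
    beta: np.ndarray                  # genes x preserved-design columns
    design_preserved: np.ndarray      # samples x preserved columns (centered coding)
    sigma2: np.ndarray                # per-gene pooled variance
    gamma_star: np.ndarray            # genes x batches, shrunk locations
    delta2_star: np.ndarray           # genes x batches, shrunk squared scales
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    prior_gamma_bar: np.ndarray       # per-batch normal prior mean
    prior_tau2: np.ndarray            # per-batch normal prior variance
    prior_a: np.ndarray               # per-batch inverse-gamma shape
    prior_b: np.ndarray               # per-batch inverse-gamma rate


def _design_matrix(batch_idx: np.ndarray, n_batches: int,
                   preserve: np.ndarray | None) -> np.ndarray:
    B = np.zeros((batch_idx.size, n_batches))
    B[np.arange(batch_idx.size), batch_idx] = 1.0
    if preserve is None or preserve.size == 0:
        return B
    return np.hstack([B, preserve])


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(g_hat, g_bar, n, d2_star, t2):
    return (t2 * n * g_hat + d2_star * g_bar) / (t2 * n + d2_star)


def _postvar(ss, n, a, b):
    return (0.5 * ss + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data: np.ndarray, g_hat: np.ndarray, d2_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500):
    """Fixed-point solution of the EB posterior for one batch (all genes)."""
    n = s_data.shape[1]
    g_old, d2_old = g_hat.copy(), d2_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d2_old, t2)
        ss = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d2_new = _postvar(ss, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d2_new - d2_old).max() / d2_old.max())
        g_old, d2_old = g_new, d2_new
        if change < conv:
            break
    return g_old, d2_old


def fit_eb_batch_model(
    matrix: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    preserve: pd.DataFrame | np.ndarray | None = None,
) -> AdjustmentModel:
    """Fit the parametric EB location/scale batch model.

    ``preserve`` holds design columns (e.g. a 0/1 diagnosis indicator)
    whose effects must survive the adjustment.
    """
    X = matrix.to_numpy(dtype=float)
    batch = pd.Series(np.asarray(batch), index=matrix.columns)
    levels = sorted(batch.unique())
    batch_idx = batch.map({b: i for i, b in enumerate(levels)}).to_numpy()
    n_batches = len(levels)
    counts = np.bincount(batch_idx, minlength=n_batches)
    if (counts < 2).any():
        bad = [levels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"batch level(s) {bad} have fewer than 2 samples")

    if preserve is not None:
        P = np.asarray(preserve, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        P = P - P.mean(axis=0)  # centered so batch dummies absorb the grand mean
    else:
        P = np.zeros((X.shape[1], 0))

    design = _design_matrix(batch_idx, n_batches, P)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("preserved design is confounded with batch (collinear design)")

    # OLS per gene (shared design): B_hat rows = genes
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    coef = coef.T                                  # genes x (n_batches + p)
    batch_coef = coef[:, :n_batches]
    beta = coef[:, n_batches:]
    alpha = batch_coef @ (counts / counts.sum())   # weighted grand mean

    stand_mean = alpha[:, None] + beta @ P.T
    resid = X - coef @ design.T
    sigma2 = (resid ** 2).mean(axis=1)
    sigma2 = np.maximum(sigma2, 1e-12)

    s_data = (X - stand_mean) / np.sqrt(sigma2)[:, None]

    gamma_hat = np.empty((X.shape[0], n_batches))
    delta2_hat = np.empty_like(gamma_hat)
    for b in range(n_batches):
        cols = batch_idx == b
        gamma_hat[:, b] = s_data[:, cols].mean(axis=1)
        delta2_hat[:, b] = s_data[:, cols].var(axis=1, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    g_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(n_batches)
    a_pr = np.empty(n_batches)
    b_pr = np.empty(n_batches)
    if n_batches == 1:
        # degenerate: nothing to shrink toward; correction is the identity
        gamma_star[:] = 0.0
        delta2_star[:] = 1.0
        a_pr[:] = b_pr[:] = np.nan
    else:
        for b in range(n_batches):
            a_pr[b] = _aprior(delta2_hat[:, b])
            b_pr[b] = _bprior(delta2_hat[:, b])
            cols = batch_idx == b
            g, d2 = _it_sol(s_data[:, cols], gamma_hat[:, b], delta2_hat[:, b],
                            g_bar[b], t2[b], a_pr[b], b_pr[b])
            gamma_star[:, b] = g
            delta2_star[:, b] = d2

    return AdjustmentModel(
        feature_ids=list(matrix.index), batch_levels=levels,
        batch_of_sample=batch_idx, alpha=alpha, beta=beta, design_preserved=P,
        sigma2=sigma2, gamma_star=gamma_star, delta2_star=delta2_star,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        prior_gamma_bar=g_bar, prior_tau2=t2, prior_a=a_pr, prior_b=b_pr,
    )


def apply_adjustment(
    matrix: pd.DataFrame,
    model: AdjustmentModel,
    batch: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Remove the fitted batch locations/scales; re-inject preserved effects.

    By default the matrix is the one the model was fitted on. Passing
    ``batch`` applies the fitted correction to new samples from the same
    batch levels (out-of-sample calibration); preserved-design effects are
    then not re-injected beyond the grand intercept, since the new
    samples' design is unknown to the model.
    """
    if list(matrix.index) != model.feature_ids:
        raise ValueError("feature set does not match the fitted model")
    X = matrix.to_numpy(dtype=float)
    if batch is None:
        stand_mean = model.alpha[:, None] + model.beta @ model.design_preserved.T
        idx = model.batch_of_sample
    else:
        labels = pd.Series(np.asarray(batch))
        unknown = set(labels) - set(model.batch_levels)
        if unknown:
            raise ValueError(f"batch level(s) {sorted(unknown)} not in the fitted model")
        lut = {b: i for i, b in enumerate(model.batch_levels)}
        idx = labels.map(lut).to_numpy()
        stand_mean = np.repeat(model.alpha[:, None], X.shape[1], axis=1)
    s_data = (X - stand_mean) / np.sqrt(model.sigma2)[:, None]
    corrected = (s_data - model.gamma_star[:, idx]) / np.sqrt(model.delta2_star[:, idx])
    out = corrected * np.sqrt(model.sigma2)[:, None] + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def adjust_stepwise(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    steps: list[str] = ("plate", "site"),
    preserve: str | None = "diagnosis",
) -> pd.DataFrame:
    """Sequential EB adjustment over the listed batch variables.

    The default order (plate, then clinical site) yields the adjusted
    "whole blood" dataset; an empty step list is the identity.
    """
    out = matrix
    P = None
    if preserve is not None:
        labels = metadata.loc[matrix.columns, preserve]
        codes = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
        P = codes
    for var in steps:
        model = fit_eb_batch_model(out, metadata.loc[out.columns, var], preserve=P)
        out = apply_adjustment(out, model)
    return out


def residualize_continuous(
    matrix: pd.DataFrame,
    covariate: pd.Series | np.ndarray,
    preserve: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene OLS residualization on a scalar covariate, diagnosis retained.

    Fits x_g ~ 1 + diagnosis + covariate and subtracts only the fitted
    covariate term, producing e.g. the "neutrophil-adjusted" dataset.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != matrix.shape[1]:
        raise ValueError("covariate length must equal sample count")
    if np.ptp(cov) == 0:
        raise ValueError("covariate has zero variance")
    cols = [np.ones_like(cov)]
    if preserve is not None:
        labels = pd.Series(np.asarray(preserve))
        codes = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
        cols.extend(codes.T)
    cols.append(cov)
    D = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(D, matrix.to_numpy(dtype=float).T, rcond=None)
    slope = coef[-1]                                # per-gene covariate slope
    out = matrix.to_numpy(dtype=float) - np.outer(slope, cov)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
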