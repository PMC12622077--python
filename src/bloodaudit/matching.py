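"""Propensity-score matching on sex and age, with balance diagnostics.

Fits a logistic model of diagnosis on sex and age, computes per-sample
propensity logits, and performs greedy 1:1 nearest-neighbour matching on
the logit without replacement to build a class-balanced training subset.
Standardized mean differences before/after matching quantify residual
covariate imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PropensityModel", "MatchedCohort", "fit_propensity",
           "match_nearest", "balance_diagnostics"]

_SEX_CODE = {"F": 1.0, "M": 0.0}


@dataclass
class PropensityModel:
    coefficients: pd.Series      # original-scale intercept + covariate coefs
    scores: pd.Series            # propensity P(case | covariates)
    logits: pd.Series
    separation_flag: bool
    covariates: list[str]


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame          # case_id, control_id, distance
    matched_ids: list
    balance: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = list(self.pairs["case_id"]) + list(self.pairs["control_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("a sample appears in more than one matched pair")


def _encode(metadata: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        v = metadata[c]
        if v.dtype == object:
            cols.append(v.map(_SEX_CODE).astype(float).to_numpy())
        else:
            cols.append(v.astype(float).to_numpy())
    return np.column_stack(cols)


def fit_propensity(
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age"),
    case_label: str = "case",
) -> PropensityModel:
    """Maximum-likelihood logistic fit of diagnosis on the covariates.

    Covariates are standardized internally for numerical stability;
    coefficients are reported back on the original scale. Quasi-separation
    is flagged when the optimizer fails to converge or coefficients blow up.
    """
    y = (metadata["diagnosis"] == case_label).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both diagnosis classes must be present")
    Xraw = _encode(metadata, covariates)
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    active = sd > 0                       # constant covariates get coefficient 0
    sd_safe = np.where(active, sd, 1.0)
    Xs = ((Xraw - mu) / sd_safe)[:, active]
    X = sm.add_constant(Xs, has_constant="add")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        caught = []
        warnings.showwarning = lambda *a, **k: caught.append(a)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
            if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 50:
                separation = True
        except Exception:
            separation = True
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
            params = np.asarray(res.params)

    # back-transform to the original covariate scale
    beta_std = np.asarray(params)
    beta = np.zeros(Xraw.shape[1])
    beta[active] = beta_std[1:] / sd_safe[active]
    intercept = float(beta_std[0]) - float((beta * mu).sum())
    coefs = pd.Series([intercept] + list(beta), index=["intercept"] + list(covariates))

    logit = intercept + Xraw @ beta
    score = 1.0 / (1.0 + np.exp(-logit))
    return PropensityModel(
        coefficients=coefs,
        scores=pd.Series(score, index=metadata.index, name="propensity"),
        logits=pd.Series(logit, index=metadata.index, name="logit"),
        separation_flag=separation,
        covariates=list(covariates),
    )


def match_nearest(
    model: PropensityModel,
    metadata: pd.DataFrame,
    caliper: Optional[float] = None,
    case_label: str = "case",
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit.

    The minority class drives the matching; its members are processed in
    descending logit order (ties broken by sample id) and each takes the
    closest still-available sample of the other class (distance ties also
    broken by sample id). Pairs farther apart than ``caliper`` (if set)
    are discarded.
    """
    is_case = metadata["diagnosis"] == case_label
    cases = list(metadata.index[is_case])
    controls = list(metadata.index[~is_case])
    if not cases or not controls:
        raise ValueError("both diagnosis classes must be present")
    minority, majority = (cases, controls) if len(cases) <= len(controls) else (controls, cases)
    minority_is_case = len(cases) <= len(controls)

    lg = model.logits
    order = sorted(minority, key=lambda s: (-lg[s], s))
    available = sorted(majority)
    rows = []
    for m in order:
        if not available:
            break
        best = min(available, key=lambda c: (abs(lg[c] - lg[m]), c))
        dist = abs(lg[best] - lg[m])
        if caliper is not None and dist > caliper:
            continue
        available.remove(best)
        case_id, control_id = (m, best) if minority_is_case else (best, m)
        rows.append((case_id, control_id, dist))
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    matched = list(pairs["case_id"]) + list(pairs["control_id"])
    cohort = MatchedCohort(pairs=pairs, matched_ids=matched)
    if not pairs.empty:
        cohort.balance = balance_diagnostics(cohort, metadata, model.covariates, model)
    return cohort


def _smd(x1: np.ndarray, x0: np.ndarray) -> tuple[float, bool]:
    m1, m0 = x1.mean(), x0.mean()
    s1, s0 = x1.var(ddof=1) if x1.size > 1 else 0.0, x0.var(ddof=1) if x0.size > 1 else 0.0
    pooled = np.sqrt((s1 + s0) / 2.0)
    if pooled == 0:
        return 0.0, True
    return float((m1 - m0) / pooled), False


def balance_diagnostics(
    cohort: MatchedCohort,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age"),
    model: Optional[PropensityModel] = None,
    case_label: str = "case",
) -> pd.DataFrame:
    """Standardized mean difference per covariate, before vs after matching."""
    if cohort.pairs.empty:
        raise ValueError("matched cohort is empty")
    enc = pd.DataFrame(_encode(metadata, covariates),
                       index=metadata.index, columns=list(covariates))
    if model is not None:
        enc["propensity_logit"] = model.logits
    is_case = metadata["diagnosis"] == case_label
    matched = metadata.index.isin(cohort.matched_ids)
    rows = []
    for c in enc.columns:
        smd_pre, flag_pre = _smd(enc.loc[is_case, c].to_numpy(),
                                 enc.loc[~is_case, c].to_numpy())
        smd_post, flag_post = _smd(enc.loc[is_case & matched, c].to_numpy(),
                                   enc.loc[~is_case & matched, c].to_numpy())
        rows.append({"covariate": c, "smd_before": smd_pre, "smd_after": smd_post,
                     "zero_variance": flag_pre or flag_post})
    return pd.DataFrame(rows).set_index("covariate")
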