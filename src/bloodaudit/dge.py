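"""Differential expression and concordance statistics.

Three tools: a SAM-style moderated t statistic with a permutation-based
false-discovery estimate; a rank-rank hypergeometric overlap (RRHO) map
comparing two signed gene rankings (e.g. the female and male
case/control contrasts) without a significance cutoff; and hypergeometric
over-representation of a query gene set against the expressed-gene
background, with Benjamini-Hochberg correction across the collection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["SAMResult", "RRHOMap", "sam_statistic", "sam_permutation_fdr",
           "rrho_map", "rrho_enrichment_zone", "ora_hypergeometric",
           "read_gmt"]


@dataclass
class SAMResult:
    d: pd.Series
    q: pd.Series
    s0: float
    n_permutations: int
    exhaustive: bool


@dataclass
class RRHOMap:
    """-log10 over-enrichment p per (top-i of A, top-j of B) grid cell."""

    minus_log10_p: pd.DataFrame    # rows: thresholds on A, cols: thresholds on B
    signed: pd.DataFrame           # sign(overlap - expected) * -log10 p
    overlap: pd.DataFrame
    universe: int
    step: int


def _group_stats(X: np.ndarray, labels: np.ndarray):
    g1, g0 = X[:, labels == 1], X[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs >= 2 samples for a pooled variance")
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g0 - m0[:, None]) ** 2).sum(axis=1)
    pooled = ss / (n1 + n0 - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n0) * pooled)
    return m1 - m0, s


def sam_statistic(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    s0: float | str = "auto",
) -> tuple[pd.Series, float]:
    """SAM moderated statistic d_g = (mean_case - mean_control) / (s_g + s0).

    ``s0="auto"`` sets the exchangeability constant to the median of the
    per-gene standard errors. With s0 = 0 the statistic reduces to the
    pooled-variance two-sample t.
    """
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "case").astype(int)
    diff, s = _group_stats(matrix.to_numpy(dtype=float), y)
    s0_val = float(np.median(s)) if s0 == "auto" else float(s0)
    d = diff / (s + s0_val)
    return pd.Series(d, index=matrix.index, name="d"), s0_val


def _perm_labels(n: int, n1: int, n_permutations: int, rng: np.random.Generator):
    """Label permutations: exhaustive when feasible, else random draws."""
    from math import comb
    total = comb(n, n1)
    if total <= n_permutations:
        perms = []
        for pos in itertools.combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(pos)] = 1
            perms.append(lab)
        return perms, True
    perms = []
    for _ in range(n_permutations):
        lab = np.zeros(n, dtype=int)
        lab[rng.choice(n, size=n1, replace=False)] = 1
        perms.append(lab)
    return perms, False


def sam_permutation_fdr(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_permutations: int = 200,
    s0: float | str = "auto",
    seed: int = 0,
) -> SAMResult:
    """Permutation false-discovery q-values for the SAM statistic.

    For each candidate threshold t (the observed |d| values), the FDR is
    the median over permutations of the number of permuted |d| >= t,
    divided by the observed count at t. A gene's q is the minimum FDR
    over thresholds at which it is called (step-up), clipped to [0, 1].
    """
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = (y == "case").astype(int)
    d_obs, s0_val = sam_statistic(matrix, y, s0=s0)
    X = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _perm_labels(len(y), int(y.sum()), n_permutations, rng)

    abs_obs = np.abs(d_obs.to_numpy())
    order = np.argsort(-abs_obs)                # descending |d|
    thresholds = abs_obs[order]
    observed_calls = np.arange(1, len(thresholds) + 1)

    perm_counts = np.empty((len(perms), len(thresholds)))
    for k, lab in enumerate(perms):
        diff, s = _group_stats(X, lab)
        abs_perm = np.sort(np.abs(diff / (s + s0_val)))
        # permuted count of |d_perm| >= t for each threshold
        perm_counts[k] = len(abs_perm) - np.searchsorted(abs_perm, thresholds, side="left")
    median_false = np.median(perm_counts, axis=0)
    fdr = median_false / observed_calls
    # step-up: q at rank r = min FDR over ranks >= r (larger call sets)
    q_sorted = np.minimum.accumulate(np.clip(fdr, 0.0, 1.0)[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return SAMResult(d=d_obs, q=pd.Series(q, index=matrix.index, name="q"),
                     s0=s0_val, n_permutations=len(perms), exhaustive=exhaustive)


def rrho_map(
    list_a: pd.Series,
    list_b: pd.Series,
    step: Optional[int] = None,
) -> RRHOMap:
    """Rank-rank hypergeometric overlap of two signed rankings.

    Both inputs are per-gene signed scores over an identical universe,
    sorted internally in descending order. For each grid cell (i, j) the
    overlap k of the top-i of A with the top-j of B is scored by the
    over-enrichment tail p = P(X >= k), X ~ Hypergeom(N, i, j).
    """
    if set(list_a.index) != set(list_b.index):
        raise ValueError("gene universes differ between the two lists")
    if list_a.index.has_duplicates or list_b.index.has_duplicates:
        raise ValueError("duplicate genes in a ranked list")
    N = len(list_a)
    if step is None:
        step = max(1, int(np.ceil(N / 100)))
    ranked_a = list(list_a.sort_values(ascending=False, kind="stable").index)
    ranked_b = list(list_b.sort_values(ascending=False, kind="stable").index)
    pos_b = {g: r for r, g in enumerate(ranked_b)}
    rank_in_b = np.array([pos_b[g] for g in ranked_a])

    grid = list(range(step, N + 1, step))
    ml10 = np.empty((len(grid), len(grid)))
    signed = np.empty_like(ml10)
    overlap = np.empty_like(ml10, dtype=int)
    # overlap(i, j) = #{genes in top-i of A with rank_in_b < j}
    for gi, i in enumerate(grid):
        head_ranks = np.sort(rank_in_b[:i])
        for gj, j in enumerate(grid):
            k = int(np.searchsorted(head_ranks, j, side="left"))
            p = float(hypergeom.sf(k - 1, N, i, j))
            v = -np.log10(max(p, 1e-320))
            ml10[gi, gj] = v
            expected = i * j / N
            signed[gi, gj] = v if k >= expected else -(-np.log10(
                max(float(hypergeom.cdf(k, N, i, j)), 1e-320)))
            overlap[gi, gj] = k
    idx = pd.Index(grid, name="top_a")
    cols = pd.Index(grid, name="top_b")
    return RRHOMap(
        minus_log10_p=pd.DataFrame(ml10, index=idx, columns=cols),
        signed=pd.DataFrame(signed, index=idx, columns=cols),
        overlap=pd.DataFrame(overlap, index=idx, columns=cols),
        universe=N, step=step,
    )


def rrho_enrichment_zone(
    rmap: RRHOMap,
    list_a: pd.Series,
    list_b: pd.Series,
) -> dict:
    """Gene set at the most significant concordant cell of the map.

    Concordance is assessed on the head-head map (top of both rankings)
    and on the tail-tail map (bottom of both); the better corner wins.
    Ties break toward the smallest i + j. Returns the intersection gene
    set at the chosen cell with its coordinates and p-value.
    """
    def _argmax(map_df: pd.DataFrame):
        arr = map_df.to_numpy()
        best = None
        for gi, i in enumerate(map_df.index):
            for gj, j in enumerate(map_df.columns):
                key = (arr[gi, gj], -(i + j))
                if best is None or key > best[0]:
                    best = (key, i, j)
        return best[1], best[2], best[0][0]

    ranked_a = list(list_a.sort_values(ascending=False, kind="stable").index)
    ranked_b = list(list_b.sort_values(ascending=False, kind="stable").index)

    i_h, j_h, v_h = _argmax(rmap.minus_log10_p)
    tail_map = rrho_map(-list_a, -list_b, step=rmap.step)
    i_t, j_t, v_t = _argmax(tail_map.minus_log10_p)

    if v_h >= v_t:
        genes = sorted(set(ranked_a[:i_h]) & set(ranked_b[:j_h]))
        return {"corner": "head-head", "i": i_h, "j": j_h,
                "minus_log10_p": v_h, "genes": genes}
    genes = sorted(set(ranked_a[-i_t:]) & set(ranked_b[-j_t:]))
    return {"corner": "tail-tail", "i": i_t, "j": j_t,
            "minus_log10_p": v_t, "genes": genes}


def ora_hypergeometric(
    query: set,
    collection: dict[str, set],
    background: set,
) -> pd.DataFrame:
    """Hypergeometric over-representation against an expressed background.

    Sets are intersected with the background before testing; the query
    must lie within the background. Exact tail sums, BH-corrected across
    the collection.
    """
    query = set(query)
    background = set(background)
    outside = query - background
    if outside:
        raise ValueError(f"query genes outside background: {sorted(outside)[:5]}")
    N, n_query = len(background), len(query)
    rows = []
    for name, genes in collection.items():
        in_bg = set(genes) & background
        k = len(in_bg & query)
        p = float(hypergeom.sf(k - 1, N, len(in_bg), n_query))
        rows.append({"set": name, "overlap": k, "set_size": len(in_bg),
                     "query_size": n_query, "background_size": N, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT gene-set collection (set name, description, members)."""
    collection = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            collection[parts[0]] = set(g for g in parts[2:] if g)
    return collection
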