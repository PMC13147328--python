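"""Rank-based comparison tests for normalization-method evaluation.

The paired comparison of per-ISTD RSD* values across methods uses the
Durbin-Conover test on a balanced complete block design (blocks = ISTD
targets, treatments = methods); comparisons of per-feature metric
distributions between methods use Dunn's all-pairs test on joint ranks.
Both report unadjusted two-sided p-values; Holm's step-down adjustment is
applied separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["holm_adjust", "durbin_conover", "dunn_all_pairs", "significance_stars"]


def holm_adjust(p) -> np.ndarray:
    """Holm step-down multiple-testing adjustment.

    Sort ascending; the k-th adjusted p-value is the running maximum of
    min(1, (m - j + 1) * p_(j)) over j <= k; returned in the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted = np.maximum.accumulate(adjusted)
    out = np.empty(m)
    out[order] = adjusted
    return out


def durbin_conover(block_matrix) -> pd.DataFrame:
    """All-pairs Durbin-Conover test on a balanced complete block design.

    ``block_matrix`` is blocks x treatments. Observations are ranked within
    each block (midranks for ties); pairwise treatment rank sums are
    compared with a t-distributed statistic whose variance comes from the
    within-block rank dispersion, df = (b - 1)(k - 1). Returns a symmetric
    DataFrame of unadjusted two-sided p-values with 1 on the diagonal.
    """
    X = np.asarray(block_matrix, dtype=float)
    columns = (
        list(block_matrix.columns)
        if isinstance(block_matrix, pd.DataFrame)
        else [f"T{i + 1}" for i in range(X.shape[1])]
    )
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a blocks x treatments matrix, >= 2 of each")
    if np.isnan(X).any():
        raise ValueError("incomplete block design: missing cells")
    b, k = X.shape
    R = np.apply_along_axis(sps.rankdata, 1, X)
    Rj = R.sum(axis=0)
    A = float(np.sum(R**2))
    C = b * k * (k + 1) ** 2 / 4.0
    D = A - C
    df = (b - 1) * (k - 1)
    if D <= 0:  # every block entirely tied: no information
        P = np.ones((k, k))
        return pd.DataFrame(P, index=columns, columns=columns)
    T1 = (k - 1) / D * float(np.sum((Rj - b * (k + 1) / 2.0) ** 2))
    shrink = 1.0 - T1 / (b * (k - 1))
    diff = Rj[:, None] - Rj[None, :]
    if shrink <= 0:
        # perfect separation of treatments: any rank-sum gap is significant
        P = np.where(diff == 0, 1.0, 0.0)
        np.fill_diagonal(P, 1.0)
        return pd.DataFrame(P, index=columns, columns=columns)
    denom = np.sqrt(2.0 * b * D / df * shrink)
    tstat = diff / denom
    P = 2.0 * sps.t.sf(np.abs(tstat), df=df)
    np.fill_diagonal(P, 1.0)
    return pd.DataFrame(np.minimum(P, 1.0), index=columns, columns=columns)


def dunn_all_pairs(groups, labels=None) -> pd.DataFrame:
    """Dunn's all-pairs comparison on jointly ranked data.

    ``groups`` is a list of 1-D value arrays. Values are ranked together
    (midranks for ties); for each pair the standardized mean-rank
    difference

        z = (mean_rank_i - mean_rank_j) /
            sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with tie term T = sum(t^3 - t) is referred to the standard normal.
    Returns a symmetric DataFrame of unadjusted two-sided p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = np.array([g.size for g in groups])
    stops = np.cumsum(sizes)
    starts = stops - sizes
    mean_ranks = np.array(
        [ranks[s:e].mean() for s, e in zip(starts, stops)]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_unit = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    k = len(groups)
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            P[i, j] = P[j, i] = p
    return pd.DataFrame(P, index=labels, columns=labels)


def significance_stars(p: float) -> str:
    """Conventional star labels: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"
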