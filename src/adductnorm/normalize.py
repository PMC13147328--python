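"""Normalization and signal-drift correction for feature tables.

Six methods share one contract: a positive normalization factor is computed
per run (sample-based methods: TIC, median) or per feature per run
(QC-based methods: FBSC-B, lomec, LMBSC, QC-RLSC); the raw value is divided
by its factor and multiplied by the median of the factors, so corrected
data stay on the original intensity scale and relative standard deviations
remain interpretable.

Sample-based methods use the whole run's signal; QC-based methods track
each feature's drift through the repeated injections of pooled QC material
and therefore correct feature-dependent drift that a single per-run scalar
cannot.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    FeatureTable,
    NormalizationResult,
    RunType,
    ValidationError,
)
from .loess import SharedGridLoess, loess_gcv_fit, DEFAULT_SPAN_GRID

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "normalize",
    "normalize_within_batches",
    "tic_factors",
    "median_factors",
    "fbsc_b_factors",
    "lomec_factors",
    "lmbsc_correct",
    "qc_rlsc_correct",
    "batch_align_mean",
]

METHODS = ("none", "tic", "median", "fbsc_b", "lomec", "lmbsc", "qc_rlsc")

#: QC runs used for drift estimation: internal QCs and their replicate
#: vials. eQCs bracket the sequence and are reserved for evaluation.
DEFAULT_QC_TYPES = (RunType.IQC, RunType.TECH_REPLICATE)


def _require_complete(table: FeatureTable) -> np.ndarray:
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("normalization requires a complete table (impute first)")
    return vals


def _qc_columns(table: FeatureTable, qc_types: Iterable[RunType | str]) -> np.ndarray:
    wanted = {RunType.coerce(t) for t in qc_types}
    return np.array([r.run_type in wanted for r in table.runs], dtype=bool)


def _clamp_factors(fac: np.ndarray, vals: np.ndarray, label: str) -> np.ndarray:
    """Clamp non-positive factors to 1e-6 x the feature median, warn once."""
    eps = 1e-6 * np.median(vals, axis=1, keepdims=True)
    eps = np.where(eps > 0, eps, 1e-12)
    bad = fac <= 0
    if bad.any():
        logger.warning("%s: clamped %d non-positive factors", label, int(bad.sum()))
        fac = np.where(bad, np.broadcast_to(eps, fac.shape), fac)
    return fac


def _result_per_run(table: FeatureTable, factors: np.ndarray, method: str) -> NormalizationResult:
    fac = pd.Series(factors, index=table.values.columns, name="factor")
    if (fac <= 0).any():
        bad = fac.index[fac <= 0][0]
        raise ValidationError(f"{method}: non-positive factor for run {bad!r}")
    rescale = float(fac.median())
    corrected = table.values.div(fac, axis=1) * rescale
    return NormalizationResult(
        table=table.with_values(corrected), factors=fac, method=method,
        rescale_constant=rescale,
    )


def _result_per_feature(table: FeatureTable, factors: np.ndarray, method: str) -> NormalizationResult:
    fac = pd.DataFrame(factors, index=table.values.index, columns=table.values.columns)
    rescale = fac.median(axis=1)
    corrected = table.values / fac * rescale.to_numpy()[:, None]
    return NormalizationResult(
        table=table.with_values(corrected), factors=fac, method=method,
        rescale_constant=rescale,
    )


# ---------------------------------------------------------------------------
# sample-based factors
# ---------------------------------------------------------------------------

def tic_factors(table: FeatureTable) -> pd.Series:
    """Per-run total ion count: the summed peak area of the run."""
    vals = _require_complete(table)
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        bad = table.values.columns[totals <= 0][0]
        raise ValidationError(f"tic: run {bad!r} has non-positive total")
    return pd.Series(totals, index=table.values.columns, name="factor")


def median_factors(table: FeatureTable) -> pd.Series:
    """Per-run median peak area across features."""
    vals = _require_complete(table)
    med = np.median(vals, axis=0)
    if (med <= 0).any():
        bad = table.values.columns[med <= 0][0]
        raise ValidationError(f"median: run {bad!r} has non-positive median")
    return pd.Series(med, index=table.values.columns, name="factor")


# ---------------------------------------------------------------------------
# QC-based factors
# ---------------------------------------------------------------------------

def _qc_pairs(table: FeatureTable, qc_mask: np.ndarray) -> list[np.ndarray]:
    """Group QC columns into injection-consecutive pairs/blocks."""
    idx = np.flatnonzero(qc_mask)
    if idx.size == 0:
        return []
    inj = table.injection_indices
    pairs: list[list[int]] = [[idx[0]]]
    for k in idx[1:]:
        if inj[k] == inj[pairs[-1][-1]] + 1:
            pairs[-1].append(k)
        else:
            pairs.append([k])
    return [np.array(p) for p in pairs]


def fbsc_b_factors(
    table: FeatureTable, qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES
) -> pd.DataFrame:
    """Bracketing-QC factors: local iQC-pair mean over grand iQC mean.

    For each run the nearest QC pair before and after it supply up to four
    QC intensities whose mean, divided by the feature's grand QC mean, is
    the run's factor. Runs outside the first/last pair use the single
    nearest pair; QC runs use their own pair.
    """
    vals = _require_complete(table)
    qc_mask = _qc_columns(table, qc_types)
    pairs = _qc_pairs(table, qc_mask)
    if not pairs:
        raise ValidationError("fbsc_b: no QC runs of the requested types")
    inj = table.injection_indices
    pair_pos = np.array([inj[p].mean() for p in pairs])
    grand = vals[:, qc_mask].mean(axis=1)
    if (grand <= 0).any():
        bad = table.values.index[grand <= 0][0]
        raise ValidationError(f"fbsc_b: feature {bad!r} has non-positive QC mean")

    pair_of_col = {int(c): pi for pi, p in enumerate(pairs) for c in p}
    factors = np.empty_like(vals)
    for j in range(vals.shape[1]):
        if j in pair_of_col:
            cols = pairs[pair_of_col[j]]
        else:
            before = np.flatnonzero(pair_pos < inj[j])
            after = np.flatnonzero(pair_pos > inj[j])
            chosen: list[np.ndarray] = []
            if before.size:
                chosen.append(pairs[before[np.argmax(pair_pos[before])]])
            if after.size:
                chosen.append(pairs[after[np.argmin(pair_pos[after])]])
            cols = np.concatenate(chosen)
        factors[:, j] = vals[:, cols].mean(axis=1) / grand
    return pd.DataFrame(factors, index=table.values.index, columns=table.values.columns)


def lomec_factors(
    table: FeatureTable,
    window_k: int = 4,
    qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES,
) -> pd.DataFrame:
    """Local-mean factors: mean of the k nearest QCs over the grand QC mean.

    Distance is in injection index; ties break toward earlier injections.
    """
    if window_k < 2:
        raise ValidationError("lomec: window_k must be >= 2")
    vals = _require_complete(table)
    qc_mask = _qc_columns(table, qc_types)
    qc_cols = np.flatnonzero(qc_mask)
    if qc_cols.size < window_k:
        raise ValidationError(
            f"lomec: need at least window_k={window_k} QC runs, have {qc_cols.size}"
        )
    inj = table.injection_indices
    grand = vals[:, qc_cols].mean(axis=1)
    if (grand <= 0).any():
        bad = table.values.index[grand <= 0][0]
        raise ValidationError(f"lomec: feature {bad!r} has non-positive QC mean")
    factors = np.empty_like(vals)
    for j in range(vals.shape[1]):
        d = np.abs(inj[qc_cols] - inj[j])
        order = np.lexsort((inj[qc_cols], d))  # tie -> earlier injection
        sel = qc_cols[order[:window_k]]
        factors[:, j] = vals[:, sel].mean(axis=1) / grand
    return pd.DataFrame(factors, index=table.values.index, columns=table.values.columns)


def lmbsc_correct(
    table: FeatureTable,
    alpha: float = 0.05,
    qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES,
) -> NormalizationResult:
    """Linear-model signal adjustment, applied only where drift is detected.

    Per feature, QC intensity is regressed on injection index by ordinary
    least squares. Only when the slope's two-sided t-test gives p < alpha
    is the feature corrected, by the ratio of the fitted line at each run's
    injection index to the line at the mean QC index; otherwise the feature
    passes through unchanged.
    """
    vals = _require_complete(table)
    qc_mask = _qc_columns(table, qc_types)
    nq = int(qc_mask.sum())
    if nq < 3:
        raise ValidationError("lmbsc: need at least 3 QC runs")
    inj = table.injection_indices
    x = inj[qc_mask]
    Y = vals[:, qc_mask]

    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = Y @ xc / sxx
    intercept = Y.mean(axis=1) - slope * x.mean()
    fitted_qc = intercept[:, None] + slope[:, None] * x[None, :]
    rss = np.sum((Y - fitted_qc) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (nq - 2) / sxx)
        # se == 0 with zero slope is a flat noiseless feature (no trend);
        # se == 0 with nonzero slope is an exact trend (certain detection)
        tstat = np.where(se > 0, slope / np.where(se > 0, se, 1.0),
                         np.where(slope == 0, 0.0, np.inf))
    pvals = 2 * sps.t.sf(np.abs(tstat), df=nq - 2)
    significant = pvals < alpha

    factors = np.ones_like(vals)
    if significant.any():
        line = intercept[significant, None] + slope[significant, None] * inj[None, :]
        center = Y.mean(axis=1)[significant, None]  # line at mean QC index
        fac = line / center
        fac = _clamp_factors(fac, vals[significant], "lmbsc")
        factors[significant] = fac
    res = _result_per_feature(table, factors, "lmbsc")
    res.corrected_fraction = float(significant.mean())  # type: ignore[attr-defined]
    return res


def qc_rlsc_correct(
    table: FeatureTable,
    degree: int = 2,
    span_grid: Sequence[float] | None = None,
    qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES,
) -> NormalizationResult:
    """QC-based robust LOESS signal correction.

    Per feature, a local polynomial drift curve is fitted to the QC
    intensities against injection index with the span chosen by GCV; the
    fitted curve evaluated at every run's injection index is the factor
    surface (clamped positive), followed by the common divide-and-rescale.
    """
    vals = _require_complete(table)
    qc_mask = _qc_columns(table, qc_types)
    if qc_mask.sum() < 5:
        raise ValidationError("qc_rlsc: need at least 5 QC runs")
    inj = table.injection_indices
    smoother = SharedGridLoess(inj[qc_mask], degree=degree, span_grid=span_grid)
    Y = vals[:, qc_mask]
    span_idx = smoother.select_spans(Y)
    factors = smoother.predict(Y, span_idx, inj)
    factors = _clamp_factors(factors, vals, "qc_rlsc")
    return _result_per_feature(table, factors, "qc_rlsc")


# ---------------------------------------------------------------------------
# dispatcher and batch alignment
# ---------------------------------------------------------------------------

def normalize(table: FeatureTable, method: str, **options) -> NormalizationResult:
    """Apply one of the six methods (or ``none``) with divide-and-rescale."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "none":
        vals = _require_complete(table)
        fac = pd.Series(1.0, index=table.values.columns, name="factor")
        return NormalizationResult(
            table=table.copy(), factors=fac, method="none", rescale_constant=1.0
        )
    if method == "tic":
        return _result_per_run(table, tic_factors(table).to_numpy(), "tic")
    if method == "median":
        return _result_per_run(table, median_factors(table).to_numpy(), "median")
    if method == "fbsc_b":
        fac = fbsc_b_factors(table, **options)
        return _result_per_feature(table, fac.to_numpy(), "fbsc_b")
    if method == "lomec":
        fac = lomec_factors(table, **options)
        return _result_per_feature(table, fac.to_numpy(), "lomec")
    if method == "lmbsc":
        return lmbsc_correct(table, **options)
    return qc_rlsc_correct(table, **options)


def batch_align_mean(
    result: NormalizationResult,
    qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES,
) -> NormalizationResult:
    """Align batches by mean QC response, per feature.

    Each batch's runs are scaled by grand mean / batch QC mean so the
    feature's QC level is the same in every batch. A single-batch input is
    returned unchanged with a warning.
    """
    table = result.table
    batches = table.batches
    labels = list(dict.fromkeys(batches))
    if len(labels) < 2:
        logger.warning("batch_align_mean: single batch, nothing to align")
        return result
    vals = table.values.to_numpy(dtype=float)
    qc_mask = _qc_columns(table, qc_types)
    scale = np.ones_like(vals)
    batch_means = {}
    for b in labels:
        cols = (batches == b) & qc_mask
        if not cols.any():
            raise ValidationError(f"batch {b!r} contains no QC runs")
        batch_means[b] = vals[:, cols].mean(axis=1)
        if (batch_means[b] <= 0).any():
            bad = table.values.index[batch_means[b] <= 0][0]
            raise ValidationError(f"batch {b!r}: zero QC mean for feature {bad!r}")
    grand = np.mean([batch_means[b] for b in labels], axis=0)
    for b in labels:
        scale[:, batches == b] = (grand / batch_means[b])[:, None]

    corrected = table.values * scale
    # fold the alignment into the factor surface so the round trip holds
    if isinstance(result.factors, pd.Series):
        base = np.broadcast_to(result.factors.to_numpy()[None, :], vals.shape)
    else:
        base = result.factors.to_numpy()
    # corrected_aligned = raw / (factor / scale) * rescale, rescale unchanged
    new_factors = base / scale
    fac_df = pd.DataFrame(new_factors, index=table.values.index,
                          columns=table.values.columns)
    return NormalizationResult(
        table=table.with_values(corrected),
        factors=fac_df,
        method=result.method + "+batch_align",
        rescale_constant=result.rescale_constant,
    )


def normalize_within_batches(
    table: FeatureTable,
    method: str,
    align: bool = True,
    qc_types: Sequence[RunType | str] = DEFAULT_QC_TYPES,
    **options,
) -> NormalizationResult:
    """Normalize each batch separately, then align batches by mean response.

    With a single batch this is plain :func:`normalize`. With several, each
    batch's columns are corrected with factors computed from that batch
    alone (per-batch rescale folded into the factor surface, so the
    corrected x factor = raw round trip still holds cell-wise), and the
    batch offsets are then removed by :func:`batch_align_mean`.
    """
    labels = list(dict.fromkeys(table.batches))
    if len(labels) < 2:
        return normalize(table, method, **options)

    vals = table.values
    fac_all = np.empty(vals.shape)
    corr_all = np.empty(vals.shape)
    batches = table.batches
    for b in labels:
        mask = batches == b
        keep = [r for r, m in zip(table.runs, mask) if m]
        sub = FeatureTable(
            values=vals.loc[:, mask].copy(),
            feature_meta=table.feature_meta.copy(),
            runs=keep,
        )
        res = normalize(sub, method, **options)
        if isinstance(res.factors, pd.Series):
            f = np.broadcast_to(res.factors.to_numpy()[None, :], sub.values.shape)
            resc = res.rescale_constant
        else:
            f = res.factors.to_numpy()
            resc = (
                res.rescale_constant.to_numpy()[:, None]
                if isinstance(res.rescale_constant, pd.Series)
                else res.rescale_constant
            )
        fac_all[:, mask] = f / resc  # fold rescale in: corrected = raw / fac
        corr_all[:, mask] = res.table.values.to_numpy()

    result = NormalizationResult(
        table=table.with_values(
            pd.DataFrame(corr_all, index=vals.index, columns=vals.columns)
        ),
        factors=pd.DataFrame(fac_all, index=vals.index, columns=vals.columns),
        method=method,
        rescale_constant=1.0,
    )
    if align:
        result = batch_align_mean(result, qc_types=qc_types)
    return result
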