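"""Missingness filtering, imputation, DNA-amount correction and PCA.

Order of operations mirrors common untargeted practice: filter features on
the fraction of missing sample runs, impute what remains from a uniform
half-minimum distribution, optionally correct sample runs for the amount of
DNA that went into the extraction, then inspect structure by PCA of the
log2 / centered / unit-variance matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import FeatureTable, RunType, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["filter_missing", "impute_half_min", "dna_conc_correct", "pca_transform"]


def filter_missing(
    table: FeatureTable, max_missing_fraction: float = 0.5
) -> tuple[FeatureTable, list[str]]:
    """Drop features missing in more than the given fraction of sample runs.

    Only sample runs enter the fraction — a feature absent from every QC but
    present in the samples is kept. The inequality is strict: a feature
    missing in exactly half the samples survives a 0.5 threshold.
    """
    sample_mask = np.array([r.run_type is RunType.SAMPLE for r in table.runs])
    if not sample_mask.any():
        raise ValidationError("filter_missing requires at least one sample run")
    sub = table.values.loc[:, sample_mask]
    frac = sub.isna().sum(axis=1) / sample_mask.sum()
    removed = table.values.index[frac > max_missing_fraction]
    kept = table.values.index.difference(removed, sort=False)
    logger.info("filter_missing: removed %d of %d features", len(removed),
                table.n_features)
    filtered = FeatureTable(
        values=table.values.loc[kept].copy(),
        feature_meta=table.feature_meta.loc[kept].copy(),
        runs=list(table.runs),
    )
    return filtered, list(removed)


def impute_half_min(table: FeatureTable, seed: int) -> FeatureTable:
    """Replace missing cells by draws from Uniform[min/2, min] per feature.

    ``min`` is the smallest observed value of the feature across all runs
    (samples and QCs alike). Observed cells are untouched; the draw is
    seeded and reproducible.
    """
    vals = table.values.to_numpy(dtype=float).copy()
    missing = np.isnan(vals)
    if not missing.any():
        return table.copy()
    n_obs = (~missing).sum(axis=1)
    if (n_obs == 0).any():
        bad = table.values.index[n_obs == 0].tolist()
        raise ValidationError(
            f"features with no observed values (filter first): {bad}"
        )
    rng = np.random.default_rng(seed)
    mins = np.nanmin(np.where(missing, np.nan, vals), axis=1)
    rows, cols = np.nonzero(missing)
    draws = rng.uniform(mins[rows] / 2.0, mins[rows])
    vals[rows, cols] = draws
    out = table.with_values(
        pd.DataFrame(vals, index=table.values.index, columns=table.values.columns)
    )
    return out


def dna_conc_correct(table: FeatureTable) -> FeatureTable:
    """Scale each sample run by mean(DNA conc) / its DNA conc.

    Dividing areas by the run's DNA concentration (ng/uL) and multiplying
    by the average concentration puts all samples on a common amount-of-DNA
    basis. QC and replicate runs are pooled after extraction and are left
    unchanged.
    """
    concs = []
    for r in table.runs:
        if r.run_type is RunType.SAMPLE:
            if r.dna_concentration is None:
                raise ValidationError(
                    f"sample run {r.run_id!r} lacks dna_concentration"
                )
            concs.append(r.dna_concentration)
    if not concs:
        raise ValidationError("no sample runs to correct")
    mean_conc = float(np.mean(concs))
    scale = np.ones(table.n_runs)
    i = 0
    for k, r in enumerate(table.runs):
        if r.run_type is RunType.SAMPLE:
            scale[k] = mean_conc / concs[i]
            i += 1
    out_vals = table.values.mul(scale, axis=1)
    return table.with_values(out_vals)


def pca_transform(table: FeatureTable) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the log2-transformed, centered, unit-variance matrix.

    Runs are the observations, features the variables. Zero-variance
    features are dropped with a log message. Component signs are fixed by
    making each component's largest-magnitude loading positive, so scores
    are reproducible across runs of the same data.

    Returns (scores as runs x components DataFrame, explained-variance
    fractions).
    """
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("pca_transform requires a complete table (impute first)")
    if (vals <= 0).any():
        raise ValidationError("pca_transform requires all values > 0 (log2)")
    logged = np.log2(vals)  # features x runs
    sd = logged.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("pca_transform: dropping %d zero-variance features",
                    int((~keep).sum()))
    if not keep.any():
        raise ValidationError("no features with nonzero variance")
    logged = logged[keep]
    sd = sd[keep]
    z = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
    x = z.T  # runs x features
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for c in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[c]))
        if vt[c, k] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    var = s**2 / (n - 1)
    total_var = z.shape[0]  # unit-variance features: total variance = n features
    explained = var / total_var
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(table.run_ids, name="run_id"),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, explained
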