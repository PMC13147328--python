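"""Robust per-feature quality metrics: RSD*, D-ratio, thresholded retention.

RSD* is the scaled median absolute deviation divided by the absolute median
(the robust analogue of the coefficient of variation); the D-ratio compares
the dispersion of technical replicates against the dispersion across study
samples — a low D-ratio marks a feature whose variation is dominated by
biology rather than measurement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from typing import Iterable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .core import FeatureTable, QcMetrics

__all__ = ["rsd_star", "d_ratio", "evaluate_features", "count_retained", "MAD_SCALE"]

#: Normal-consistency constant for the MAD, as in R's mad() default.
MAD_SCALE = 1.4826


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def rsd_star(values: Iterable[float]) -> float:
    """Robust relative standard deviation: 1.4826 * MAD / |median|."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("rsd_star needs at least 2 finite values")
    med = np.median(x)
    if med == 0:
        raise ValueError("rsd_star undefined for zero median")
    return MAD_SCALE * _mad(x) / abs(med)


def d_ratio(rep_values: Iterable[float], sample_values: Iterable[float]) -> float:
    """Dispersion ratio MAD(replicates) / MAD(samples).

    The 1.4826 consistency constant cancels between numerator and
    denominator and is omitted.
    """
    rep = np.asarray(list(rep_values), dtype=float)
    sam = np.asarray(list(sample_values), dtype=float)
    rep = rep[np.isfinite(rep)]
    sam = sam[np.isfinite(sam)]
    if rep.size < 2 or sam.size < 2:
        raise ValueError("d_ratio needs at least 2 values in each group")
    mad_sam = _mad(sam)
    if mad_sam == 0:
        raise ValueError("d_ratio undefined: zero sample MAD (degenerate feature)")
    return _mad(rep) / mad_sam


def evaluate_features(
    table: "FeatureTable",
    rsd_threshold: float = 0.2,
    dratio_threshold: float = 0.4,
    replicate_types: Iterable[str] = ("tech_replicate",),
) -> "QcMetrics":
    """Score every feature and flag those passing both thresholds.

    RSD* is computed over the technical-replicate runs, the D-ratio with
    replicates as numerator group and study samples as denominator group.
    Pass flags use strict ``<``; ``retained`` requires both. Features whose
    sample MAD is zero get an infinite D-ratio (never retained) rather than
    an error, so one degenerate row cannot abort a table-level evaluation.
    """
    from .core import QcMetrics, RunType, ValidationError

    rep_types = {RunType.coerce(t) for t in replicate_types}
    rep_mask = np.array([r.run_type in rep_types for r in table.runs])
    sam_mask = np.array([r.run_type is RunType.SAMPLE for r in table.runs])
    if rep_mask.sum() < 2 or sam_mask.sum() < 2:
        raise ValidationError(
            "evaluate_features needs >= 2 replicate runs and >= 2 sample runs"
        )
    vals = table.values.to_numpy(dtype=float)
    rep = vals[:, rep_mask]
    sam = vals[:, sam_mask]

    rep_med = np.median(rep, axis=1)
    rep_mad = np.median(np.abs(rep - rep_med[:, None]), axis=1)
    sam_med = np.median(sam, axis=1)
    sam_mad = np.median(np.abs(sam - sam_med[:, None]), axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = MAD_SCALE * rep_mad / np.abs(rep_med)
        dr = np.where(sam_mad > 0, rep_mad / np.where(sam_mad > 0, sam_mad, 1.0),
                      np.inf)
    rsd = np.where(rep_med == 0, np.inf, rsd)

    rsd_pass = rsd < rsd_threshold
    dratio_pass = dr < dratio_threshold
    frame = pd.DataFrame(
        {
            "rsd_star": rsd,
            "d_ratio": dr,
            "rsd_pass": rsd_pass,
            "dratio_pass": dratio_pass,
            "retained": rsd_pass & dratio_pass,
        },
        index=table.values.index,
    )
    return QcMetrics(frame=frame, rsd_threshold=rsd_threshold,
                     dratio_threshold=dratio_threshold)


def count_retained(metrics: "QcMetrics") -> tuple[int, int, int]:
    """(n passing RSD*, n passing D-ratio, n passing both)."""
    f = metrics.frame
    return (
        int(f["rsd_pass"].sum()),
        int(f["dratio_pass"].sum()),
        int(f["retained"].sum()),
    )
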