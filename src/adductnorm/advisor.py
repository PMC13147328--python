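"""Target-guided estimation of upstream peak-picking parameters.

Operates on extracted-ion-chromatogram (EIC) summaries of a handful of
well-behaved target compounds to suggest the mass-accuracy window (ppm),
the chromatographic peak-width bounds (seconds) and the minimum detection
fraction used when grouping peaks into features. It deliberately does not
re-run peak detection: the inputs are plain (run_id, target_id, rt, mz,
intensity) points exported from whatever did.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EicTrace",
    "read_eics",
    "estimate_ppm",
    "estimate_peakwidth",
    "suggest_min_fraction",
]


@dataclass
class EicTrace:
    """One target's extracted ion chromatogram in one run."""

    target_id: str
    run_id: str
    rt: np.ndarray         # seconds, ascending
    mz: np.ndarray         # Da
    intensity: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.rt.size == self.mz.size == self.intensity.size):
            raise ValueError("rt, mz, intensity must be equal length")
        if np.any(np.diff(self.rt) < 0):
            order = np.argsort(self.rt, kind="stable")
            self.rt, self.mz, self.intensity = (
                self.rt[order], self.mz[order], self.intensity[order]
            )
        if (self.mz <= 0).any():
            raise ValueError("m/z must be > 0")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")


def read_eics(path: str | Path) -> list[EicTrace]:
    """Load EIC points from a CSV with run_id, target_id, rt, mz, intensity."""
    df = pd.read_csv(path)
    needed = {"run_id", "target_id", "rt", "mz", "intensity"}
    if not needed <= set(df.columns):
        raise ValueError(f"EIC CSV needs columns {sorted(needed)}")
    traces = []
    for (tid, rid), g in df.groupby(["target_id", "run_id"], sort=True):
        traces.append(
            EicTrace(target_id=str(tid), run_id=str(rid),
                     rt=g["rt"].to_numpy(), mz=g["mz"].to_numpy(),
                     intensity=g["intensity"].to_numpy())
        )
    return traces


def estimate_ppm(traces: Sequence[EicTrace], apex_gate: float = 0.5) -> float:
    """Observed mass spread of one target across runs, in ppm.

    Collects the m/z of points at or above ``apex_gate`` times each trace's
    apex intensity (restricting to the peak proper, where a single mass
    dominates the spectrum) and returns the maximum pairwise absolute m/z
    difference relative to the median m/z, times 1e6.
    """
    mzs = []
    for tr in traces:
        if tr.intensity.size == 0:
            continue
        apex = tr.intensity.max()
        if apex <= 0:
            continue
        mzs.append(tr.mz[tr.intensity >= apex_gate * apex])
    if not mzs:
        raise ValueError("no points above the intensity floor")
    mz = np.concatenate(mzs)
    if mz.size < 2:
        raise ValueError("need at least 2 qualifying points to estimate ppm")
    spread = float(mz.max() - mz.min())
    return spread / float(np.median(mz)) * 1e6


def _trace_width(tr: EicTrace, height_frac: float) -> float:
    inten = tr.intensity
    apex_idx = int(np.argmax(inten))
    apex = inten[apex_idx]
    q = np.quantile(inten, 0.25)
    baseline = float(np.median(inten[inten <= q])) if np.any(inten <= q) else 0.0
    height = apex - baseline
    if height <= 0:
        raise ValueError(f"trace {tr.target_id}/{tr.run_id} is flat")
    cut = baseline + height_frac * height
    above = inten >= cut
    # contiguous region around the apex
    left = apex_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = apex_idx
    while right < inten.size - 1 and above[right + 1]:
        right += 1
    # sub-scan refinement: interpolate the threshold crossing linearly
    t_left = tr.rt[left]
    if left > 0:
        lo, hi = inten[left - 1], inten[left]
        if hi > lo:
            t_left = tr.rt[left - 1] + (cut - lo) / (hi - lo) * (tr.rt[left] - tr.rt[left - 1])
    t_right = tr.rt[right]
    if right < inten.size - 1:
        hi, lo = inten[right], inten[right + 1]
        if hi > lo:
            t_right = tr.rt[right] + (hi - cut) / (hi - lo) * (tr.rt[right + 1] - tr.rt[right])
    width = t_right - t_left
    scan = float(np.min(np.diff(tr.rt))) if tr.rt.size > 1 else 0.0
    return max(width, scan)


def estimate_peakwidth(
    traces: Sequence[EicTrace], height_frac: float = 0.05
) -> tuple[float, float]:
    """(min, max) peak width across traces, seconds.

    Width is measured where the trace stays at or above ``height_frac`` of
    the baseline-subtracted apex, contiguously around the apex; the
    baseline is the median of the lowest intensity quartile. Widths are
    floored at one scan interval.
    """
    widths = [_trace_width(tr, height_frac) for tr in traces]
    if not widths:
        raise ValueError("no traces given")
    return float(min(widths)), float(max(widths))


def suggest_min_fraction(
    detection_rates: Mapping[str, float] | Iterable[float], safety: float = 0.75
) -> float:
    """Conservative minFraction from per-target detection rates.

    Returns ``safety * min(rate)`` rounded down to two decimals and floored
    at 0.01, guaranteeing the rarest known-real target would still be
    grouped into a feature.
    """
    rates = (
        list(detection_rates.values())
        if isinstance(detection_rates, Mapping)
        else list(detection_rates)
    )
    if not rates:
        raise ValueError("no detection rates given")
    if any(not 0 < r <= 1 for r in rates):
        raise ValueError("detection rates must lie in (0, 1]")
    raw = safety * min(rates)
    return max(0.01, float(np.floor(raw * 100) / 100))
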