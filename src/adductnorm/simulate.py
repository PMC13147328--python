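"""Seeded generator of LC-MS run sequences and feature tables.

Emulates the injection design of a pooled-QC untargeted study: a lead-in of
external QCs (eQCs), blocks of randomized samples each followed by a pair of
internal QCs (iQCs, the second vial flagged as a technical replicate), and a
lead-out of eQCs. On top of per-feature true abundances the generator layers
feature-dependent multiplicative signal drift (sinusoid plus linear trend in
injection order), per-batch column effects, multiplicative technical noise,
DNA-amount scaling of sample runs, QC dilution, and intensity-dependent
censoring to missing. Ground truth is returned alongside the observed table
so corrections can be scored against what a perfect method could achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable, RunMetadata, RunType, ValidationError
from .metrics import rsd_star

__all__ = ["SimConfig", "SimTruth", "build_sequence", "simulate_table", "truth_drift_rsd"]


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Intensity-like quantities are in arbitrary peak-area units; "cv"
    parameters are standard deviations on the natural-log scale (for small
    values these coincide with coefficients of variation).
    """

    n_samples: int = 50
    n_features: int = 200
    n_istd: int = 3
    block_size: int = 10          # samples between iQC pairs
    n_eqc: int = 4                # eQCs at sequence start and again at end
    n_batches: int = 1
    biological_cv: float = 0.3    # log-sd of sample abundances
    tech_cv: float = 0.05         # log-sd of multiplicative measurement noise
    drift_amplitude_range: tuple[float, float] = (0.1, 0.3)
    drift_period_range: tuple[float, float] = (30.0, 60.0)   # injections
    drift_slope_range: tuple[float, float] = (-0.2, 0.2)     # total over sequence
    batch_effect_sd: float = 0.0  # log-sd of per-feature per-batch offsets
    qc_dilution: float = 0.8      # pooled QC level relative to mean sample
    intensity_range: tuple[float, float] = (1e4, 1e7)  # baseline log-uniform
    lod: float = 5e3              # censoring midpoint intensity
    missing_steepness: float = 1e-3  # sigmoid slope per intensity unit
    frac_high_biovar: float = 0.0    # fraction of features with inflated biology
    high_biovar_factor: float = float(np.sqrt(10.0))  # multiplier on the log-sd
    dna_conc_mean: float = 50.0   # ng/uL
    dna_conc_cv: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_features < 1 or self.n_istd < 0 or self.n_istd > self.n_features:
            raise ValidationError("need 0 <= n_istd <= n_features, n_features >= 1")
        if self.block_size < 1 or self.n_batches < 1:
            raise ValidationError("block_size and n_batches must be >= 1")
        if not 0 < self.qc_dilution <= 1:
            raise ValidationError("qc_dilution must be in (0, 1]")
        for name in ("drift_amplitude_range", "drift_period_range",
                     "drift_slope_range", "intensity_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValidationError(f"{name} must be (lo, hi) with hi >= lo")
        if not 0 <= self.frac_high_biovar <= 1:
            raise ValidationError("frac_high_biovar must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for k in ("drift_amplitude_range", "drift_period_range",
                  "drift_slope_range", "intensity_range"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Ground truth behind a simulated table.

    ``true_abundance`` holds the biological signal only (drift, batch,
    noise and DNA-amount scaling all excluded); ISTD rows are constant.
    ``drift_surface`` and ``batch_factors`` are the multiplicative
    distortions a perfect correction would remove.
    """

    true_abundance: pd.DataFrame   # features x runs
    drift_surface: pd.DataFrame    # features x runs, > 0
    batch_factors: pd.DataFrame    # features x batches
    istd_ids: frozenset[str]


def build_sequence(config: SimConfig) -> list[RunMetadata]:
    """Lay out the injection sequence implied by the config.

    ``n_eqc`` eQCs, then blocks of up to ``block_size`` samples each followed
    by an iQC pair whose second member is a technical replicate, then
    ``n_eqc`` closing eQCs. Batches are contiguous near-equal spans.
    """
    config.validate()
    entries: list[tuple[str, RunType]] = []
    for i in range(config.n_eqc):
        entries.append((f"eQC{i + 1:02d}", RunType.EQC))
    n_blocks = -(-config.n_samples // config.block_size)  # ceil
    s = 0
    for b in range(n_blocks):
        for _ in range(min(config.block_size, config.n_samples - s)):
            s += 1
            entries.append((f"S{s:03d}", RunType.SAMPLE))
        entries.append((f"iQC{2 * b + 1:02d}", RunType.IQC))
        entries.append((f"iQC{2 * b + 2:02d}", RunType.TECH_REPLICATE))
    for i in range(config.n_eqc):
        entries.append((f"eQC{config.n_eqc + i + 1:02d}", RunType.EQC))

    n = len(entries)
    spans = np.array_split(np.arange(n), config.n_batches)
    batch_of = np.empty(n, dtype=object)
    for b, span in enumerate(spans):
        batch_of[span] = f"B{b + 1}"
    return [
        RunMetadata(run_id=rid, injection_index=j + 1, run_type=rt, batch=batch_of[j])
        for j, (rid, rt) in enumerate(entries)
    ]


def simulate_table(config: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Generate an observed feature table and its ground truth.

    Per feature ``i`` and injection ``j``::

        observed = abundance * drift_i(j) * batch_i(b_j) * noise
        drift_i(j) = 1 + a_i sin(2 pi j / P_i + phi_i) + s_i j / N

    with sample abundances mu_i * lognormal(biological_cv), pooled-QC
    abundances at ``qc_dilution`` times the mean sample abundance, and ISTD
    abundances exactly ``mu_i`` in every run. Every sample-run cell is
    additionally scaled by the run's relative DNA amount (the nuisance that
    DNA-concentration correction removes); QC runs are pooled after
    extraction and are not. Low intensities are censored to missing with
    probability
    ``sigmoid(missing_steepness * (lod - value))``. Fully deterministic
    given the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    runs = build_sequence(config)
    n_runs = len(runs)
    nf = config.n_features

    sample_mask = np.array([r.run_type is RunType.SAMPLE for r in runs])
    n_samples = int(sample_mask.sum())

    # feature identities: ISTDs first, then untargeted features
    feature_ids = [f"ISTD{i + 1:02d}" for i in range(config.n_istd)] + [
        f"F{i + 1:04d}" for i in range(nf - config.n_istd)
    ]
    istd_mask = np.zeros(nf, dtype=bool)
    istd_mask[: config.n_istd] = True

    lo, hi = config.intensity_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=nf))
    # ISTDs are spiked at comfortable levels: upper half of the range
    if config.n_istd:
        baseline[istd_mask] = np.exp(
            rng.uniform(np.log(np.sqrt(lo * hi)), np.log(hi), size=config.n_istd)
        )

    bio_sd = np.full(nf, config.biological_cv)
    n_high = int(round(config.frac_high_biovar * (nf - config.n_istd)))
    if n_high:
        high_idx = rng.choice(np.flatnonzero(~istd_mask), size=n_high, replace=False)
        bio_sd[high_idx] = config.biological_cv * config.high_biovar_factor

    # DNA concentration per sample run
    conc = config.dna_conc_mean * np.exp(
        config.dna_conc_cv * rng.standard_normal(n_samples)
    )
    dna_scale = conc / config.dna_conc_mean

    # true abundances (biology only; DNA-amount scaling is a removable
    # distortion applied below, like drift)
    abundance = np.empty((nf, n_runs))
    sample_ab = baseline[:, None] * np.exp(
        bio_sd[:, None] * rng.standard_normal((nf, n_samples))
    )
    sample_ab[istd_mask] = baseline[istd_mask, None]
    qc_ab = config.qc_dilution * sample_ab.mean(axis=1)
    qc_ab[istd_mask] = baseline[istd_mask]
    abundance[:, sample_mask] = sample_ab
    abundance[:, ~sample_mask] = qc_ab[:, None]
    # per-run DNA-amount surface: sample runs scale with the amount of DNA
    # that entered the extraction, QCs are pooled and do not
    dna_surface = np.ones(n_runs)
    dna_surface[sample_mask] = dna_scale

    # drift surface
    j = np.arange(1, n_runs + 1, dtype=float)
    a = rng.uniform(*config.drift_amplitude_range, size=nf)
    period = rng.uniform(*config.drift_period_range, size=nf)
    phi = rng.uniform(0, 2 * np.pi, size=nf)
    slope = rng.uniform(*config.drift_slope_range, size=nf)
    drift = (
        1.0
        + a[:, None] * np.sin(2 * np.pi * j[None, :] / period[:, None] + phi[:, None])
        + slope[:, None] * j[None, :] / n_runs
    )
    drift = np.clip(drift, 0.05, None)  # keep multiplicative surface positive

    # per-feature per-batch column effects
    batch_labels = sorted({r.batch for r in runs}, key=lambda b: int(b[1:]))
    bfac = np.exp(config.batch_effect_sd * rng.standard_normal((nf, len(batch_labels))))
    if config.batch_effect_sd == 0:
        bfac[:] = 1.0
    batch_idx = np.array([batch_labels.index(r.batch) for r in runs])
    batch_surface = bfac[:, batch_idx]

    noise = np.exp(config.tech_cv * rng.standard_normal((nf, n_runs)))
    observed = abundance * dna_surface[None, :] * drift * batch_surface * noise

    # intensity-dependent censoring
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(-config.missing_steepness * (config.lod - observed)))
    censored = rng.random((nf, n_runs)) < p_miss
    observed = observed.astype(float)
    observed[censored] = np.nan

    run_ids = [r.run_id for r in runs]
    # attach DNA concentrations to sample runs
    runs_full: list[RunMetadata] = []
    s_i = 0
    for r in runs:
        if r.run_type is RunType.SAMPLE:
            runs_full.append(
                RunMetadata(r.run_id, r.injection_index, r.run_type, r.batch,
                            float(conc[s_i]))
            )
            s_i += 1
        else:
            runs_full.append(r)

    values = pd.DataFrame(observed, index=pd.Index(feature_ids, name="feature_id"),
                          columns=run_ids)
    mz = np.round(rng.uniform(70.0, 700.0, size=nf), 4)
    rt = np.round(rng.uniform(60.0, 900.0, size=nf), 2)
    feature_meta = pd.DataFrame(
        {"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id")
    )
    table = FeatureTable(values=values, feature_meta=feature_meta, runs=runs_full)
    truth = SimTruth(
        true_abundance=pd.DataFrame(abundance, index=values.index, columns=run_ids),
        drift_surface=pd.DataFrame(drift, index=values.index, columns=run_ids),
        batch_factors=pd.DataFrame(bfac, index=values.index, columns=batch_labels),
        istd_ids=frozenset(np.array(feature_ids)[istd_mask].tolist()),
    )
    return table, truth


def truth_drift_rsd(truth: SimTruth, runs: list[RunMetadata]) -> pd.Series:
    """Per-feature RSD* of the true abundances over sample runs.

    The floor a perfect drift/batch/DNA correction could reach: biological
    variation only.
    """
    sample_cols = [r.run_id for r in runs if r.run_type is RunType.SAMPLE]
    if len(sample_cols) < 2:
        raise ValidationError("need at least 2 sample runs")
    sub = truth.true_abundance[sample_cols]
    return sub.apply(lambda row: rsd_star(row.to_numpy()), axis=1)
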