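# Methods

This note documents the models, conventions and numerical choices behind
`adductnorm`, in the order data flow through the pipeline.

## Data model

A feature table is a features × runs matrix of non-negative peak areas
with per-run metadata (1-based strictly increasing injection index, run
type ∈ {sample, iqc, eqc, tech_replicate}, batch label, optional DNA
concentration in ng/µL for samples) and per-feature annotations (m/z in
Da, RT in seconds). Missing values are a dedicated sentinel (NaN in
memory, empty cell or NA token on disk); zero is a valid measured
intensity and never treated as missing, because gap filling upstream of
this package already distinguishes "no peak found" from "low signal". Run
order is defined by injection index, not file order; readers re-sort and
log when they differ. Feature identity is the string id — m/z and RT are
annotations, not keys.

## Filtering, imputation, DNA correction

Features missing in strictly more than `max_missing_fraction` (default
0.5) of the **sample** runs are removed; QC runs never enter the fraction,
since pooled QCs are diluted relative to the average sample and miss real
features more often. Remaining gaps in feature *i* are filled with
independent draws from `Uniform[min_i/2, min_i]`, where `min_i` is the
smallest observed value of the feature across **all** runs (the minimum is
not restricted to samples; the choice is logged). Filtering precedes
imputation, and imputation precedes normalization-factor estimation. The
left-censoring missingness mechanism in the simulator (see below) is what
makes a half-minimum scheme appropriate; it would be biased under
missingness unrelated to intensity.

DNA-concentration correction multiplies each sample-run column by
`mean(conc) / conc_run`, the mean being the arithmetic mean over sample
runs. QC runs are pooled after extraction and are left unchanged.

## Normalization contract

Every method computes strictly positive factors — per run for the
sample-based methods, per feature per run for the QC-based ones — and
applies

    corrected = raw / factor × median(factor)

where the median is over runs (sample-based) or over that feature's
factors (feature-based). The rescale step keeps corrected data on the
original intensity scale so relative standard deviations stay
interpretable, and makes `corrected × factor / rescale = raw` an exact
round trip (asserted in tests at 1e-9 relative). Fitted factors that come
out non-positive (a pathological LOESS or linear extrapolation) are
clamped to 1e-6 × the feature median with a warning, rather than aborting
a 10⁴-feature run for one degenerate curve.

Methods:

- **TIC**: factor = per-run summed intensity. **Median**: factor = per-run
  median intensity. Both assume most features do not change between runs;
  a minority of strongly varying features violates that and leaks
  biological variation into every feature (see "Known artifacts").
- **FBSC-B** (bracketing-QC correction): internal-QC injections are
  grouped into pairs by consecutive injection indices; for each run the
  nearest pair before and after it contribute up to four QC intensities
  whose mean, divided by the feature's grand QC mean, is the factor. Runs
  before the first (after the last) pair use the single nearest pair; QC
  runs use their own pair. The exact bracket definition is this package's
  choice and is configurable to use all QCs instead of iQCs only.
- **lomec** (local-mean correction): factor = mean of the `window_k = 4`
  QC runs nearest in injection index (ties toward earlier injections) over
  the grand QC mean. `window_k` equal to the number of QCs reduces to unit
  factors.
- **LMBSC**: ordinary least squares of QC intensity on injection index per
  feature; only when the slope's two-sided t-test gives p < α (default
  0.05) is the feature corrected, by the ratio of the fitted line at each
  run's index to the line at the mean QC index. Fitting on QC runs (not
  all runs) keeps the estimate independent of biology; the ratio form
  keeps the divide-and-rescale contract.
- **QC-RLSC**: per feature, a tricube-weighted local polynomial (degree 2
  by default) is fitted to QC intensity against injection index; the span
  is chosen from the grid {0.20, 0.25, …, 0.95} by generalized
  cross-validation, GCV = n·RSS / (n − tr L)², with the smoother matrix L
  assembled explicitly (its rows are the local weighted-least-squares
  coefficient vectors, so the trace is exact). Candidate spans with
  tr L > n − 1 are discarded: near-interpolating fits have no residual
  degrees of freedom and a meaningless score. The fitted curve evaluated
  at every run's injection index is the factor surface; outside the QC
  range the boundary fitted values are extended as constants rather than
  extrapolated. The smoother is evaluated directly at sample positions
  (no linear interpolation between QCs). Because the hat matrix depends
  only on the shared QC injection grid, the per-span matrices are computed
  once and applied to all features at matrix speed.

The QC set for the QC-based methods defaults to iQC + technical-replicate
runs; eQCs bracket the sequence, sit far from most samples, and are kept
out of factor estimation so they remain available as evaluation-only QCs.
This is configurable.

**Batch alignment.** With several declared batches, each batch is
normalized separately (per-batch rescale folded into the factor surface so
the cell-wise round trip still holds) and then aligned by mean response:
per feature, every run in batch *b* is scaled by grand mean / batch-QC
mean. Batch membership is always user-declared input; the package never
infers batches from the data.

## Quality metrics

RSD\* = 1.4826 · MAD(x) / |median(x)|, the robust analogue of the
coefficient of variation; the 1.4826 normal-consistency constant matches
the R `mad()` default, so thresholds are comparable with common practice.
The D-ratio is MAD(replicates) / MAD(samples); the constant cancels. The
replicate group is the technical-replicate runs (second iQC vials), not
all QCs — QCs used to *compute* normalization factors would otherwise
score the methods on their own training data. Retention requires RSD\* <
r and D-ratio < d with strict inequalities (defaults 0.2 / 0.4; 0.3 / 0.5
suit noisier studies). A feature whose sample MAD is zero receives an
infinite D-ratio (never retained) instead of raising, so one degenerate
row cannot abort a table-level evaluation. For ISTD-style evaluation the
same RSD\* is computed over sample runs; imputed cells are included.

## Comparison statistics

- **Durbin–Conover** (balanced complete blocks only): within-block
  midranks; pairwise treatment rank-sum differences are referred to a
  t-distribution with (b−1)(k−1) degrees of freedom using the within-block
  rank dispersion, following Conover's textbook form. The implementation
  is validated against an exhaustive within-block permutation oracle on
  3×3 designs and is type-I calibrated by simulation (2,000 null
  replicates, rate 0.05 ± 0.02). When the blocks agree perfectly the
  shrink term vanishes; any nonzero rank-sum gap is then reported as p = 0
  and ties as p = 1.
- **Dunn's all-pairs test**: joint midranks with the tie-corrected
  variance N(N+1)/12 − Σ(t³−t)/(12(N−1)); two-sided normal p-values. For
  two groups z² equals the Kruskal–Wallis H (tested identity).
- **Holm** step-down adjustment, applied separately from the tests.

Both tests are rank-based and hence invariant to strictly monotone
transforms of the data.

## The simulator

The generator emulates a pooled-QC exposome study: `n_eqc` eQCs, blocks of
`block_size` samples each followed by an iQC pair (second vial =
technical replicate), `n_eqc` closing eQCs; batches are contiguous
near-equal spans. Per feature *i* and injection *j*:

    observed = abundance × dna(j) × drift_i(j) × batch_i(b_j) × e^(τZ)
    drift_i(j) = 1 + a_i sin(2πj/P_i + φ_i) + s_i j/N   (clipped ≥ 0.05)

Baselines are log-uniform over 10⁴–10⁷ (ISTDs from the upper half —
standards are spiked at comfortable levels); sample abundances multiply
the baseline by a lognormal with log-sd `biological_cv` (default 0.3, with
an optional fraction of features at √10 × that, i.e. ten-fold variance);
pooled-QC abundances are `qc_dilution` (default 0.8) times the feature's
mean sample abundance; ISTD abundances are exactly the baseline in every
run. DNA-amount scaling `dna(j)` applies to all features of sample runs
only (QCs are pooled after extraction) and is excluded from the stored
ground truth, which is biology-only. Cells are censored to missing with
probability `sigmoid(steepness × (lod − value))` — low values vanish more
often, the mechanism that justifies half-minimum imputation. Drift
amplitudes default to U(0.1, 0.3), periods to U(30, 60) injections
(oscillatory components of LC-MS drift over a multi-hour sequence; the
separate linear term covers slow monotone decay, default U(−0.2, 0.2)
total), technical noise to 5% (log-sd). Identical configs (including the
seed) give bit-identical output.

What the simulator does **not** model: retention-time shifts (alignment is
upstream), scan-level chromatograms, correlated noise between co-eluting
features, matrix-dependent ionization suppression, and missingness
unrelated to intensity. Passing tests therefore demonstrate correct
behavior under multiplicative drift with censoring-driven missingness,
not robustness to every failure mode of real acquisitions.

## Problem sizes and verification

Tests validate hand-computable cases exactly, properties (round trips,
invariances, determinism) on mid-size simulations (≈100 features × 70
runs), and study-scale behavior on 500 features × 116 runs (72 samples in
blocks of 4, QCs every 6 injections) — large enough for stable medians,
small enough that the full suite runs in well under a minute. Type-I
calibration uses 2,000 replicates per test. The acceptance script uses the
same sizes.

One expectation is knowingly not met: under purely sinusoidal drift with
periods drawn from U(30, 60) over a ~103-injection QC window, features
with fewer than ≈2.5 complete cycles carry a real residual linear
component, so LMBSC corrects ≈9–11% of features rather than the α = 5%
one would expect if the sinusoid were orthogonal to a linear trend. The
test asserting the α-sized fraction is left failing rather than widened:
the method is detecting a genuine trend, and hiding that would misstate
both the method and the simulator.

## Advisor conventions

The ppm estimate gates EIC points at ≥50% of each trace's apex intensity
(approximating a restricted window with a single mass peak per spectrum)
and reports max pairwise |Δm/z| / median(m/z) × 10⁶; it deliberately
reports the *measured* spread and leaves applying a vendor floor to the
caller. Peak width is measured where the trace stays contiguously at or
above 5% of the baseline-subtracted apex (baseline = median of the lowest
intensity quartile), with the threshold crossings interpolated linearly
between scans and the result floored at one scan interval. The suggested
`minFraction` is 0.75 × the rarest target's detection rate, rounded down
to two decimals and floored at 0.01 — rare-but-real targets must survive
grouping, and missingness filtering downstream removes what over-detection
lets through.

## Known artifacts reproduced on purpose

Sample-based (TIC/median) normalization under heterogeneous biology
inflates the sample-run RSD\* of stable features (the per-run scalar
carries the biological variation of dominant features into everything)
while *lowering* their D-ratio — the inflated sample MAD sits in the
denominator — without improving replicate precision. A better-looking
D-ratio after sample-based normalization is therefore not evidence of a
better method; both the metrics tests and the acceptance script quantify
this joint direction.
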