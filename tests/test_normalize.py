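import numpy as np
import pandas as pd
import pytest

from adductnorm import (
    SimConfig,
    ValidationError,
    batch_align_mean,
    fbsc_b_factors,
    filter_missing,
    impute_half_min,
    lmbsc_correct,
    lomec_factors,
    median_factors,
    normalize,
    normalize_within_batches,
    qc_rlsc_correct,
    rsd_star,
    simulate_table,
    tic_factors,
)
from adductnorm.normalize import METHODS
from conftest import make_table


def istd_sample_rsd(table, truth):
    cols = [r.run_id for r in table.runs if r.run_type.value == "sample"]
    return np.median(
        [rsd_star(table.values.loc[i, cols].to_numpy()) for i in sorted(truth.istd_ids)]
    )


def prepared(table, seed=0):
    return impute_half_min(filter_missing(table)[0], seed=seed)


# ---------------------------------------------------------------------------
# contract: divide by factor, rescale by the median factor
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", METHODS)
def test_round_trip_reconstructs_raw(method, drifting_table):
    table, _, _ = drifting_table
    imp = prepared(table)
    res = normalize(imp, method)
    back = res.reconstruct_raw()
    scale = imp.values.abs().to_numpy().max()
    assert np.allclose(back.to_numpy(), imp.values.to_numpy(), atol=1e-9 * scale)


@pytest.mark.parametrize("method", METHODS)
def test_rescaled_factor_median_is_one(method, drifting_table):
    """After rescale, the median applied per-cell divisor is 1, so corrected
    data stay on the raw intensity scale."""
    table, _, _ = drifting_table
    imp = prepared(table)
    res = normalize(imp, method)
    if isinstance(res.factors, pd.Series):
        applied = res.factors / res.rescale_constant
        assert np.isclose(np.median(applied), 1.0, atol=1e-9)
    else:
        applied = res.factors.div(res.rescale_constant, axis=0)
        med = applied.median(axis=1)
        assert np.allclose(med, 1.0, atol=1e-9)


@pytest.mark.parametrize("method", METHODS)
def test_driftless_noiseless_table_is_fixed_point(method):
    cfg = SimConfig(n_samples=30, n_features=20, n_istd=2, biological_cv=0.0,
                    tech_cv=0.0, drift_amplitude_range=(0.0, 0.0),
                    drift_slope_range=(0.0, 0.0), qc_dilution=1.0,
                    dna_conc_cv=0.0, lod=0.0, seed=4)
    table, _ = simulate_table(cfg)
    res = normalize(table, method)
    assert np.allclose(res.table.values.to_numpy(), table.values.to_numpy(),
                       rtol=1e-9)


def test_unknown_method_rejected(drifting_table):
    table, _, _ = drifting_table
    with pytest.raises(ValidationError):
        normalize(prepared(table), "quantile")


def test_order_invariance_under_feature_permutation(drifting_table):
    """Relabeling feature order permutes the output identically."""
    table, _, _ = drifting_table
    imp = prepared(table)
    perm = np.random.default_rng(0).permutation(imp.n_features)
    shuffled = imp.with_values(imp.values.iloc[perm])
    for method in ("tic", "qc_rlsc"):
        a = normalize(imp, method).table.values.iloc[perm]
        b = normalize(shuffled, method).table.values
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)


# ---------------------------------------------------------------------------
# sample-based methods
# ---------------------------------------------------------------------------

def test_tic_hand_arithmetic():
    t = make_table(np.array([[2.0, 1.0], [4.0, 2.0], [6.0, 3.0]]),
                   ["sample", "sample"])
    fac = tic_factors(t)
    assert fac.tolist() == [12.0, 6.0]
    res = normalize(t, "tic")
    # rescale by median(12, 6) = 9
    expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
    assert np.allclose(res.table.values.to_numpy(), expected)


def test_tic_scale_invariance():
    rng = np.random.default_rng(1)
    col = rng.uniform(10, 100, 5)
    t = make_table(np.column_stack([col, 2 * col]), ["sample", "sample"])
    res = normalize(t, "tic")
    out = res.table.values.to_numpy()
    assert np.allclose(out[:, 0], out[:, 1])


def test_median_hand_arithmetic():
    vals = np.array([[5.0, 10.0], [10.0, 20.0], [20.0, 40.0]])  # medians 10, 20
    t = make_table(vals, ["sample", "sample"])
    fac = median_factors(t)
    assert fac.tolist() == [10.0, 20.0]
    res = normalize(t, "median")
    assert np.allclose(res.table.values.to_numpy(), vals * np.array([1.5, 0.75]))


def test_median_robust_to_single_outlier_feature():
    rng = np.random.default_rng(2)
    vals = rng.uniform(10, 20, size=(9, 2))
    spiked = np.vstack([vals, [[15.0, 1e6]]])
    t_plain = make_table(vals, ["sample", "sample"])
    t_spiked = make_table(spiked, ["sample", "sample"])
    assert not np.allclose(tic_factors(t_spiked).iloc[1], tic_factors(t_plain).iloc[1],
                           rtol=0.5)
    assert np.allclose(np.median(spiked, axis=0), median_factors(t_spiked),
                       rtol=0.1)


# ---------------------------------------------------------------------------
# QC-based methods
# ---------------------------------------------------------------------------

def test_fbsc_bracket_hand_arithmetic():
    """Bracketing pairs at 100 and 120 with grand mean 110 give factor 1."""
    types = ["sample", "iqc", "tech_replicate", "sample", "iqc",
             "tech_replicate", "sample"]
    vals = [[50.0, 100.0, 100.0, 60.0, 120.0, 120.0, 70.0]]
    t = make_table(vals, types)
    fac = fbsc_b_factors(t)
    # middle sample bracketed by both pairs: (100+100+120+120)/4 / 110 = 1
    assert np.isclose(fac.iloc[0, 3], 1.0)
    # leading sample uses nearest single pair: 100/110
    assert np.isclose(fac.iloc[0, 0], 100.0 / 110.0)
    # QC runs use their own pair
    assert np.isclose(fac.iloc[0, 1], 100.0 / 110.0)
    assert np.isclose(fac.iloc[0, 4], 120.0 / 110.0)


def test_fbsc_equal_qcs_identity(drifting_table):
    table, _, _ = drifting_table
    imp = prepared(table)
    qc_mask = imp.run_mask({"iqc", "tech_replicate"})
    vals = imp.values.to_numpy().copy()
    vals[:, qc_mask] = vals[:, [np.flatnonzero(qc_mask)[0]]]
    flat = imp.with_values(pd.DataFrame(vals, index=imp.values.index,
                                        columns=imp.values.columns))
    fac = fbsc_b_factors(flat)
    assert np.allclose(fac.to_numpy(), 1.0)


def test_fbsc_corrects_step_drift_at_pair_boundary():
    """A step change located exactly at an iQC pair is removed."""
    cfg = SimConfig(n_samples=32, n_features=30, n_istd=3, block_size=8,
                    drift_amplitude_range=(0.0, 0.0), drift_slope_range=(0.0, 0.0),
                    tech_cv=0.02, lod=0.0, seed=6)
    table, truth = simulate_table(cfg)
    # impose a x2 step halfway through the sequence
    half = table.n_runs // 2
    vals = table.values.to_numpy().copy()
    vals[:, half:] *= 2.0
    stepped = table.with_values(pd.DataFrame(vals, index=table.values.index,
                                             columns=table.values.columns))
    imp = prepared(stepped)
    qc_cols = [r.run_id for r in imp.runs if r.run_type.value in ("iqc", "tech_replicate")]
    before = np.median([rsd_star(imp.values.loc[i, qc_cols]) for i in imp.values.index])
    res = normalize(imp, "fbsc_b")
    after = np.median([rsd_star(res.table.values.loc[i, qc_cols])
                       for i in res.table.values.index])
    assert after < before


def test_lomec_window_equal_to_all_qcs_is_identity(drifting_table):
    table, _, _ = drifting_table
    imp = prepared(table)
    n_qc = int(imp.run_mask({"iqc", "tech_replicate"}).sum())
    fac = lomec_factors(imp, window_k=n_qc)
    assert np.allclose(fac.to_numpy(), 1.0, rtol=1e-12)


def test_lomec_rejects_tiny_window(drifting_table):
    table, _, _ = drifting_table
    with pytest.raises(ValidationError):
        lomec_factors(prepared(table), window_k=1)


def test_lomec_reduces_istd_rsd_under_linear_drift():
    cfg = SimConfig(n_samples=48, n_features=50, n_istd=5, block_size=6,
                    drift_amplitude_range=(0.0, 0.0), drift_slope_range=(0.6, 0.6),
                    tech_cv=0.05, dna_conc_cv=0.0, lod=0.0, seed=13)
    table, truth = simulate_table(cfg)
    imp = prepared(table)
    base = istd_sample_rsd(normalize(imp, "none").table, truth)
    corr = istd_sample_rsd(normalize(imp, "lomec").table, truth)
    assert corr < 0.5 * base


def test_lmbsc_flat_qcs_identity():
    types = (["sample"] * 3 + ["iqc", "tech_replicate"]) * 3
    vals = np.tile(np.array([[100.0]]), (1, len(types)))
    t = make_table(vals, types)
    res = lmbsc_correct(t)
    assert res.corrected_fraction == 0.0
    assert np.allclose(res.table.values.to_numpy(), vals)


def test_lmbsc_removes_exact_linear_trend():
    """Noiseless 100 + 2*index QCs: detected, and the corrected values have
    zero slope against injection index."""
    types = (["sample"] * 3 + ["iqc", "tech_replicate"]) * 4
    idx = np.arange(1, len(types) + 1, dtype=float)
    vals = (100.0 + 2.0 * idx)[None, :]
    t = make_table(vals, types)
    res = lmbsc_correct(t, alpha=0.05)
    assert res.corrected_fraction == 1.0
    out = res.table.values.to_numpy()[0]
    slope = np.polyfit(idx, out, 1)[0]
    assert abs(slope) < 1e-6


def test_lmbsc_alpha_limits(drifting_table):
    """alpha -> 0 never corrects; alpha = 1 always corrects."""
    table, _, _ = drifting_table
    imp = prepared(table)
    res0 = lmbsc_correct(imp, alpha=1e-300)
    assert res0.corrected_fraction == 0.0
    assert np.allclose(res0.table.values.to_numpy(), imp.values.to_numpy())
    res1 = lmbsc_correct(imp, alpha=1.0)
    assert res1.corrected_fraction == 1.0


def test_qc_rlsc_flat_qc_signal_identity():
    types = (["sample"] * 2 + ["iqc", "tech_replicate"]) * 3
    rng = np.random.default_rng(0)
    vals = rng.uniform(50, 150, (4, len(types)))
    qc_mask = np.array([t in ("iqc", "tech_replicate") for t in types])
    vals[:, qc_mask] = 80.0
    t = make_table(vals, types)
    res = qc_rlsc_correct(t)
    assert np.allclose(res.table.values.to_numpy(), vals, rtol=1e-9)


def test_qc_rlsc_flattens_smooth_drift_in_qcs():
    """Noiseless sinusoid (amplitude 0.3, period 40) sampled by QCs every 6
    injections: corrected iQC values are constant within 2%."""
    cfg = SimConfig(n_samples=72, n_features=20, n_istd=2, block_size=4,
                    drift_amplitude_range=(0.3, 0.3), drift_period_range=(40, 40),
                    drift_slope_range=(0.1, 0.1), tech_cv=0.0, lod=0.0, seed=17)
    table, _ = simulate_table(cfg)
    res = normalize(prepared(table), "qc_rlsc")
    qc_cols = [r.run_id for r in table.runs
               if r.run_type.value in ("iqc", "tech_replicate")]
    qc = res.table.values[qc_cols].to_numpy()
    spread = np.abs(qc / np.median(qc, axis=1, keepdims=True) - 1).max()
    assert spread < 0.02


def test_qc_based_methods_reduce_istd_rsd_under_drift(drifting_table):
    table, truth, _ = drifting_table
    imp = prepared(table)
    base = istd_sample_rsd(normalize(imp, "none").table, truth)
    for method in ("qc_rlsc", "lomec", "fbsc_b"):
        corr = istd_sample_rsd(normalize(imp, method).table, truth)
        assert corr < base, method


def test_sample_based_methods_inflate_istd_rsd():
    """With a minority of high-biological-variance features, per-run scalar
    factors import biological variation into the ISTDs."""
    cfg = SimConfig(n_samples=50, n_features=200, n_istd=5,
                    frac_high_biovar=0.1, drift_amplitude_range=(0.0, 0.0),
                    drift_slope_range=(0.0, 0.0), tech_cv=0.05, dna_conc_cv=0.0,
                    lod=0.0, seed=23)
    table, truth = simulate_table(cfg)
    imp = prepared(table)
    base = istd_sample_rsd(normalize(imp, "none").table, truth)
    for method in ("tic", "median"):
        assert istd_sample_rsd(normalize(imp, method).table, truth) > base, method


# ---------------------------------------------------------------------------
# batch alignment
# ---------------------------------------------------------------------------

def test_batch_align_hand_arithmetic():
    """Batch QC means 100 and 200 scale to the grand mean 150 each."""
    types = ["iqc", "tech_replicate", "sample", "iqc", "tech_replicate", "sample"]
    batches = ["B1"] * 3 + ["B2"] * 3
    vals = [[100.0, 100.0, 90.0, 200.0, 200.0, 180.0]]
    t = make_table(vals, types, batches=batches)
    res = batch_align_mean(normalize(t, "none"))
    out = res.table.values.to_numpy()[0]
    assert np.allclose(out[:3], np.array([150.0, 150.0, 135.0]))
    assert np.allclose(out[3:], np.array([150.0, 150.0, 135.0]))
    back = res.reconstruct_raw().to_numpy()[0]
    assert np.allclose(back, vals[0])


def test_batch_align_single_batch_returns_input(drifting_table):
    table, _, _ = drifting_table
    res = normalize(prepared(table), "none")
    aligned = batch_align_mean(res)
    assert aligned.table.values.equals(res.table.values)


def test_batch_align_removes_pc1_batch_separation():
    from sklearn.metrics import silhouette_score
    from adductnorm import pca_transform

    cfg = SimConfig(n_samples=40, n_features=80, n_istd=3, n_batches=2,
                    batch_effect_sd=0.5, tech_cv=0.05, lod=0.0, seed=31)
    table, _ = simulate_table(cfg)
    imp = prepared(table)

    def sil(tab):
        scores, _ = pca_transform(tab)
        return silhouette_score(scores[["PC1"]].to_numpy(), tab.batches)

    before = sil(normalize(imp, "none").table)
    after = sil(normalize_within_batches(imp, "none", align=True).table)
    assert after < before


def test_within_batch_round_trip(drifting_table):
    cfg = SimConfig(n_samples=40, n_features=30, n_istd=2, n_batches=2,
                    batch_effect_sd=0.4, tech_cv=0.05, lod=0.0, seed=37)
    table, _ = simulate_table(cfg)
    imp = prepared(table)
    res = normalize_within_batches(imp, "median", align=True)
    back = res.reconstruct_raw().to_numpy()
    scale = imp.values.abs().to_numpy().max()
    assert np.allclose(back, imp.values.to_numpy(), atol=1e-9 * scale)
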