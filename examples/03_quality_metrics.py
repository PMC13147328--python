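"""Score features with robust QC metrics and apply retention thresholds.

RSD* (1.4826 * MAD / |median| of the technical replicates) measures pure
measurement noise; the D-ratio (MAD of replicates over MAD of samples)
asks whether that noise is small compared to the biological spread.
Features pass with RSD* < 0.2 and D-ratio < 0.4 (strict inequalities).
"""

from adductnorm import (
    SimConfig, count_retained, evaluate_features, filter_missing,
    impute_half_min, normalize, simulate_table,
)

cfg = SimConfig(n_samples=50, n_features=400, n_istd=3,
                drift_amplitude_range=(0.2, 0.3), tech_cv=0.08, seed=23)
table, _ = simulate_table(cfg)
imputed = impute_half_min(filter_missing(table)[0], seed=0)

for method in ("none", "qc_rlsc"):
    corrected = normalize(imputed, method).table
    metrics = evaluate_features(corrected, rsd_threshold=0.2, dratio_threshold=0.4)
    n_rsd, n_dr, n_ret = count_retained(metrics)
    print(f"{method:8s}: {n_rsd} pass RSD*, {n_dr} pass D-ratio, "
          f"{n_ret} retained of {imputed.n_features}")
print("\nDrift correction moves replicate spread below the RSD* threshold, "
      "so many more features survive filtering — the main practical payoff "
      "of QC-based normalization.")
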