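"""Correct feature-dependent signal drift with QC-based methods.

Internal standards (ISTDs) are spiked at a constant level, so their spread
across sample runs is purely technical. Under multiplicative drift the
QC-based corrections (QC-RLSC, lomec, FBSC-B) should shrink that spread
sharply, while the significance-gated linear model (LMBSC) only acts on
features with a real linear trend.
"""

import numpy as np

from adductnorm import (
    SimConfig, filter_missing, impute_half_min, normalize, rsd_star,
    simulate_table,
)

cfg = SimConfig(n_samples=72, n_features=300, n_istd=6, block_size=4,
                drift_amplitude_range=(0.3, 0.3), tech_cv=0.05,
                dna_conc_cv=0.0, lod=0.0, seed=11)
table, truth = simulate_table(cfg)
imputed = impute_half_min(filter_missing(table)[0], seed=0)

istds = sorted(truth.istd_ids)
sample_cols = [r.run_id for r in table.runs if r.run_type.value == "sample"]


def istd_rsd(tab):
    return np.median([rsd_star(tab.values.loc[i, sample_cols]) for i in istds])


base = istd_rsd(normalize(imputed, "none").table)
print(f"median ISTD sample-run RSD* without correction: {base:.3f}")
for method in ("qc_rlsc", "lomec", "fbsc_b", "lmbsc"):
    corrected = istd_rsd(normalize(imputed, method).table)
    print(f"  after {method:8s}: {corrected:.3f}  "
          f"({100 * (1 - corrected / base):.0f}% reduction)")
print("\nAn RSD* near the technical noise level (~0.05 here) means the "
      "drift has been removed; smaller reductions flag methods that model "
      "the drift poorly.")
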