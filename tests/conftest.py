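import numpy as np
import pandas as pd
import pytest

from adductnorm import FeatureTable, RunMetadata, SimConfig, simulate_table


def make_table(values, run_types, batches=None, conc=None, feature_ids=None,
               injection_indices=None):
    """Hand-build a FeatureTable from a 2-D array and per-run type labels."""
    values = np.asarray(values, dtype=float)
    n_feat, n_runs = values.shape
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(n_feat)]
    if batches is None:
        batches = ["B1"] * n_runs
    if conc is None:
        conc = [None] * n_runs
    if injection_indices is None:
        injection_indices = list(range(1, n_runs + 1))
    runs = [
        RunMetadata(run_id=f"R{j + 1}", injection_index=injection_indices[j],
                    run_type=run_types[j], batch=batches[j],
                    dna_concentration=conc[j])
        for j in range(n_runs)
    ]
    vals = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                        columns=[r.run_id for r in runs])
    meta = pd.DataFrame(
        {"mz": np.linspace(100, 400, n_feat), "rt": np.linspace(60, 600, n_feat)},
        index=vals.index,
    )
    return FeatureTable(values=vals, feature_meta=meta, runs=runs)


@pytest.fixture(scope="session")
def drifting_table():
    """Mid-size simulated table with drift, complete (no censoring)."""
    cfg = SimConfig(n_samples=48, n_features=100, n_istd=4, block_size=8,
                    drift_amplitude_range=(0.25, 0.25), tech_cv=0.05,
                    lod=0.0, seed=42)
    table, truth = simulate_table(cfg)
    return table, truth, cfg


@pytest.fixture()
def mixed_small_table():
    """3 features x 8 runs covering all four run types."""
    rng = np.random.default_rng(0)
    vals = rng.uniform(50, 150, size=(3, 8))
    types = ["eqc", "sample", "sample", "iqc", "tech_replicate",
             "sample", "sample", "eqc"]
    conc = [None, 40.0, 60.0, None, None, 50.0, 50.0, None]
    return make_table(vals, types, conc=conc)
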