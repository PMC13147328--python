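import numpy as np
import pytest

from adductnorm import (
    ValidationError,
    dna_conc_correct,
    filter_missing,
    impute_half_min,
    pca_transform,
    simulate_table,
    SimConfig,
)
from conftest import make_table

M = np.nan


class TestFilterMissing:
    def _table(self, row):
        """One feature over 10 samples + 2 QCs at the end."""
        types = ["sample"] * 10 + ["iqc", "tech_replicate"]
        return make_table([row], types)

    def test_majority_missing_removed_boundary_kept(self):
        """>50% missing among samples removes; exactly 50% keeps."""
        six = [M] * 6 + [1.0] * 4 + [1.0, 1.0]
        _, removed = filter_missing(self._table(six), 0.5)
        assert removed == ["F1"]
        five = [M] * 5 + [1.0] * 5 + [1.0, 1.0]
        kept, removed = filter_missing(self._table(five), 0.5)
        assert removed == [] and kept.n_features == 1

    def test_qc_missingness_ignored(self):
        row = [1.0] * 10 + [M, M]
        kept, removed = filter_missing(self._table(row), 0.5)
        assert removed == [] and kept.n_features == 1

    def test_idempotent(self):
        rows = [[M] * 6 + [1.0] * 4 + [1, 1], [1.0] * 12]
        types = ["sample"] * 10 + ["iqc", "tech_replicate"]
        t = make_table(rows, types)
        once, _ = filter_missing(t, 0.5)
        twice, removed2 = filter_missing(once, 0.5)
        assert removed2 == []
        assert twice.values.equals(once.values)

    def test_requires_sample_runs(self):
        t = make_table([[1.0, 2.0]], ["iqc", "tech_replicate"])
        with pytest.raises(ValidationError):
            filter_missing(t)


class TestImputeHalfMin:
    def test_draws_lie_in_half_min_interval(self):
        t = make_table([[8.0, 12.0, M, M, M]], ["sample"] * 5)
        out = impute_half_min(t, seed=0)
        imputed = out.values.to_numpy()[0, 2:]
        assert np.all((imputed >= 4.0) & (imputed <= 8.0))
        # observed untouched
        assert out.values.iloc[0, 0] == 8.0 and out.values.iloc[0, 1] == 12.0

    def test_no_missing_is_identity(self, mixed_small_table):
        out = impute_half_min(mixed_small_table, seed=1)
        assert out.values.equals(mixed_small_table.values)

    def test_seeded_and_reproducible(self):
        t = make_table([[8.0, 12.0, M, M, M]], ["sample"] * 5)
        a = impute_half_min(t, seed=7).values
        b = impute_half_min(t, seed=7).values
        c = impute_half_min(t, seed=8).values
        assert a.equals(b)
        assert not a.equals(c)

    def test_all_missing_feature_rejected(self):
        t = make_table([[M, M, M]], ["sample"] * 3)
        with pytest.raises(ValidationError):
            impute_half_min(t, seed=0)

    def test_min_taken_across_all_runs(self):
        """The feature minimum includes QC runs, not just samples."""
        t = make_table([[100.0, M, 10.0]], ["sample", "sample", "iqc"])
        out = impute_half_min(t, seed=0)
        v = out.values.iloc[0, 1]
        assert 5.0 <= v <= 10.0


class TestDnaConcCorrect:
    def test_hand_factors(self):
        t = make_table([[10.0, 10.0, 10.0]], ["sample", "sample", "iqc"],
                       conc=[50.0, 100.0, None])
        out = dna_conc_correct(t)
        # mean conc 75 -> factors 75/50=1.5 and 75/100=0.75
        assert np.allclose(out.values.to_numpy()[0], [15.0, 7.5, 10.0])

    def test_equal_concentrations_identity(self):
        t = make_table([[10.0, 20.0, 30.0]], ["sample", "sample", "sample"],
                       conc=[50.0, 50.0, 50.0])
        out = dna_conc_correct(t)
        assert np.allclose(out.values.to_numpy(), t.values.to_numpy())

    def test_qc_columns_unchanged(self, mixed_small_table):
        out = dna_conc_correct(mixed_small_table)
        qc_mask = mixed_small_table.run_mask({"iqc", "eqc", "tech_replicate"})
        assert np.allclose(out.values.to_numpy()[:, qc_mask],
                           mixed_small_table.values.to_numpy()[:, qc_mask])

    def test_inverse_reproduces_input(self, mixed_small_table):
        out = dna_conc_correct(mixed_small_table)
        concs = [r.dna_concentration for r in mixed_small_table.runs
                 if r.dna_concentration is not None]
        mean = np.mean(concs)
        i = 0
        for j, r in enumerate(mixed_small_table.runs):
            if r.dna_concentration is not None:
                back = out.values.iloc[:, j] * r.dna_concentration / mean
                assert np.allclose(back, mixed_small_table.values.iloc[:, j])
                i += 1
        assert i == len(concs)

    def test_missing_concentration_rejected(self):
        t = make_table([[1.0, 2.0]], ["sample", "sample"], conc=[50.0, None])
        with pytest.raises(ValidationError):
            dna_conc_correct(t)


class TestPcaTransform:
    def test_variance_fractions_sum_to_one(self, mixed_small_table):
        scores, explained = pca_transform(mixed_small_table)
        assert explained.sum() <= 1 + 1e-9
        # all components kept for 3 features: full variance recovered
        assert np.isclose(explained.sum(), 1.0)

    def test_duplicated_runs_have_identical_scores(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(10, 100, size=(5, 4))
        vals = np.hstack([vals, vals[:, [0]]])  # run 5 duplicates run 1
        t = make_table(vals, ["sample"] * 5)
        scores, _ = pca_transform(t)
        assert np.allclose(scores.iloc[0], scores.iloc[4], atol=1e-8)

    def test_scores_orthogonal(self, drifting_table):
        table, _, _ = drifting_table
        from adductnorm import filter_missing, impute_half_min
        imp = impute_half_min(filter_missing(table)[0], seed=0)
        scores, _ = pca_transform(imp)
        g = scores.to_numpy().T @ scores.to_numpy()
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(g)).max()

    def test_batch_effect_separates_on_pc1(self):
        """Two strongly offset batches split along PC1 (positive silhouette)."""
        from sklearn.metrics import silhouette_score

        cfg = SimConfig(n_samples=40, n_features=60, n_batches=2,
                        batch_effect_sd=1.0, tech_cv=0.05, lod=0.0, seed=21)
        table, _ = simulate_table(cfg)
        imp = impute_half_min(filter_missing(table)[0], seed=0)
        scores, _ = pca_transform(imp)
        sil = silhouette_score(scores[["PC1"]].to_numpy(), imp.batches)
        assert sil > 0

    def test_nonpositive_values_rejected(self):
        t = make_table([[0.0, 1.0, 2.0]], ["sample"] * 3)
        with pytest.raises(ValidationError):
            pca_transform(t)
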