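"""Transcriptional-component correction and the autocorrelation score."""

import numpy as np
import pandas as pd
import pytest

from ekaryo.fgmp import (AutocorrelationParams, autocorrelation_dgi,
                         autocorrelation_table, correct_profiles,
                         fit_components)
from ekaryo.preprocess import center_to_reference
from ekaryo.synthetic import (CNAEvent, CohortSpec, simulate_cohort,
                              simulate_reference_compendium)


class TestFitComponents:
    def test_recovers_rank_one_axis(self, tiny_genome):
        rng = np.random.default_rng(0)
        load = rng.normal(size=(tiny_genome.n_genes, 1))
        ref = simulate_reference_compendium(tiny_genome, 40, 1, seed=1,
                                            component_loadings=load,
                                            noise_sd=0.0)
        comps = fit_components(ref, 1)
        cos = abs(load[:, 0] @ comps.loadings[:, 0]) / np.linalg.norm(load)
        assert cos > 0.999

    def test_k_zero_empty(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 10, 2, seed=0)
        comps = fit_components(ref, 0)
        assert comps.k == 0

    def test_variance_ordering_and_orthonormality(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 50, 4, seed=2)
        comps = fit_components(ref, 4)
        assert (np.diff(comps.explained_variance) <= 1e-9).all()
        gram = comps.loadings.T @ comps.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-10)

    def test_k_too_large_errors(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 10, 2, seed=0)
        with pytest.raises(ValueError):
            fit_components(ref, 10)

    def test_save_load_roundtrip(self, tiny_genome, tmp_path):
        ref = simulate_reference_compendium(tiny_genome, 20, 3, seed=3)
        comps = fit_components(ref, 3)
        comps.save(tmp_path / "c.tsv", tmp_path / "c.json")
        back = type(comps).load(tmp_path / "c.tsv", tmp_path / "c.json")
        assert np.allclose(back.loadings, comps.loadings)
        assert back.training_samples == 20


class TestCorrectProfiles:
    def test_empty_components_identity(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 10, 0, seed=0)
        comps = fit_components(ref, 0)
        out = correct_profiles(ref, comps)
        assert np.allclose(out.values.values, ref.values.values)

    def test_vector_in_span_residual_zero(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 40, 2, seed=1)
        comps = fit_components(ref, 2)
        v = comps.loadings @ np.array([3.0, -2.0])
        cohort = ref  # reuse annotation; replace values with in-span vectors
        vals = pd.DataFrame(np.tile(v[:, None], (1, 3)),
                            index=ref.values.index,
                            columns=["a", "b", "c"])
        from dataclasses import replace
        samples = pd.DataFrame({"sample_id": ["a", "b", "c"],
                                "tissue_class": "tumour",
                                "model_label": "m", "batch_id": "b"})
        cohort = replace(ref, values=vals, samples=samples)
        out = correct_profiles(cohort, comps)
        assert np.abs(out.values.values).max() < 1e-10

    def test_residual_orthogonal_and_idempotent(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 50, 3, seed=2)
        comps = fit_components(ref, 3)
        spec = CohortSpec(n_samples=10, aberration_prevalence=0.5, seed=3)
        cohort, _ = simulate_cohort(tiny_genome, spec)
        once = correct_profiles(cohort, comps)
        inner = comps.loadings.T @ once.values.values
        scale = np.abs(once.values.values).max()
        assert np.abs(inner).max() < 1e-8 * max(scale, 1.0)
        twice = correct_profiles(once, comps)
        assert np.allclose(once.values.values, twice.values.values, atol=1e-10)

    def test_residual_variance_not_larger(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 50, 3, seed=4)
        comps = fit_components(ref, 3)
        spec = CohortSpec(n_samples=8, aberration_prevalence=0.5,
                          n_shared_components=3, seed=5)
        cohort, _ = simulate_cohort(tiny_genome, spec)
        comp = center_to_reference(cohort, None)
        out = correct_profiles(comp, comps)
        assert (out.values.var(axis=0).values
                <= comp.values.var(axis=0).values + 1e-12).all()

    def test_low_overlap_errors(self, tiny_genome):
        ref = simulate_reference_compendium(tiny_genome, 20, 2, seed=0)
        comps = fit_components(ref, 2)
        spec = CohortSpec(n_samples=3, seed=0)
        cohort, _ = simulate_cohort(tiny_genome, spec)
        sub = cohort.with_genes(np.arange(cohort.n_genes) < cohort.n_genes // 3)
        comps.gene_ids = [g for g in comps.gene_ids
                          if g in set(sub.genes["gene_id"])]
        # now shrink the cohort's annotation overlap below 50% instead
        bad = comps.__class__(loadings=comps.loadings[:5],
                              gene_ids=comps.gene_ids[:5],
                              explained_variance=comps.explained_variance,
                              training_samples=20)
        with pytest.raises(ValueError, match="shared"):
            correct_profiles(cohort, bad)

    def test_correction_improves_cna_recovery(self, tiny_genome):
        """Residualizing against 3 planted confounders raises the per-gene
        correlation between the matrix and the true shift pattern."""
        rng = np.random.default_rng(6)
        load = rng.normal(size=(tiny_genome.n_genes, 3))
        ref = simulate_reference_compendium(tiny_genome, 80, 3, seed=7,
                                            component_loadings=load,
                                            component_sd=0.6, noise_sd=0.1)
        comps = fit_components(ref, 3)
        ev = CNAEvent(region="1", direction="gain", probability=0.5, shift=0.4)
        spec = CohortSpec(n_samples=40, event_catalogue=[ev],
                          n_shared_components=3, component_loadings=load,
                          component_sd=0.6, gene_noise_sd=0.1,
                          sample_effect_sd=0.0, seed=8)
        cohort, truth_record = simulate_cohort(tiny_genome, spec)
        carriers = truth_record.carriers()
        non_carriers = [s for s in cohort.values.columns if s not in carriers]
        comp = center_to_reference(cohort, non_carriers)
        corrected = correct_profiles(comp, comps)
        truth = (tiny_genome.genes["chromosome"] == "1").astype(float).values
        truth = truth - truth.mean()

        def mean_corr(matrix):
            X = matrix.values[list(carriers)].values
            rs = [np.corrcoef(truth, X[:, j])[0, 1] for j in range(X.shape[1])]
            return np.mean(rs)

        assert mean_corr(corrected) > mean_corr(comp)


class TestAutocorrelation:
    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        chrom = np.repeat(["1", "2"], 5000)
        assert abs(autocorrelation_dgi(x, chrom)) < 0.05

    def test_block_shift_raises_score(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 5000)
        shifted = base.copy()
        shifted[1000:1500] += 5.0
        chrom = np.repeat("1", 5000)
        assert (autocorrelation_dgi(shifted, chrom)
                > autocorrelation_dgi(base, chrom) + 0.1)

    def test_linear_gradient_near_one(self):
        x = np.linspace(0, 1, 2000)
        assert autocorrelation_dgi(x, np.repeat("1", 2000)) > 0.99

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            out = autocorrelation_dgi(np.zeros(100), np.repeat("1", 100))
        assert out == 0.0

    def test_lag_boundary_not_straddled(self):
        """A shift on one chromosome only does not leak correlation through
        the boundary: score equals the weighted within-chromosome value."""
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0, 1, 1000) + 50.0  # huge offset across the boundary
        x = np.concatenate([a, b])
        chrom = np.repeat(["1", "2"], 1000)
        within = 0.5 * (autocorrelation_dgi(a, np.repeat("1", 1000))
                        + autocorrelation_dgi(b, np.repeat("2", 1000)))
        assert autocorrelation_dgi(x, chrom) == pytest.approx(within, abs=1e-12)

    def test_ranks_prevalence_levels(self, small_genome):
        """Mean autocorrelation score increases with true aberration burden.

        The score is computed within chromosomes, so a whole-chromosome shift
        is invisible to it (it adds a constant the correlation removes); the
        burden gradient therefore uses half-chromosome events, centred to an
        external diploid reference so high-prevalence shifts survive centring.
        """
        from dataclasses import replace
        means = []
        for level, prev in enumerate((0.05, 0.25, 0.5, 0.8)):
            catalogue = [CNAEvent(region=(str(c + 1), 0, 15_000_000),
                                  direction="gain" if c % 2 == 0 else "loss",
                                  probability=prev, shift=0.4)
                         for c in range(5)]
            per_seed = []
            for rep in range(5):
                seed = 100 * level + rep
                spec = CohortSpec(n_samples=40, event_catalogue=catalogue,
                                  seed=seed)
                cohort, _ = simulate_cohort(small_genome, spec)
                ref, _ = simulate_cohort(small_genome, CohortSpec(
                    n_samples=30, tissue_class="normal", seed=50_000 + seed))
                comp = replace(cohort, values=cohort.values.sub(
                    ref.values.median(axis=1), axis=0))
                per_seed.append(autocorrelation_table(comp)["autocorr_dgi"].mean())
            means.append(np.mean(per_seed))
        assert means == sorted(means)
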