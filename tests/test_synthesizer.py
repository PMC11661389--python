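"""The synthetic-data generator and the direct-vs-indirect harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from indirectgwas import (
    InputError,
    Projection,
    SimulationConfig,
    direct_scan,
    evaluate,
    gwas_fidelity,
    random_boolean_definitions,
    random_projections,
    simulate_binary_features,
    simulate_genotypes,
    simulate_phenotypes,
    validate_direct_vs_indirect,
)
from indirectgwas.synthesizer import filter_min_observations, inverse_rank_normal


class TestGenotypes:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_individuals=100, n_variants=30, seed=7)
        np.testing.assert_array_equal(simulate_genotypes(cfg), simulate_genotypes(cfg))

    def test_different_seed_differs(self):
        a = simulate_genotypes(SimulationConfig(n_individuals=100, n_variants=30, seed=1))
        b = simulate_genotypes(SimulationConfig(n_individuals=100, n_variants=30, seed=2))
        assert not np.array_equal(a, b)

    def test_symmetric_maf_means_concentrate_near_one(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants=50, maf_range=(0.5, 0.5), seed=3)
        G = simulate_genotypes(cfg)
        assert np.all(np.abs(G.mean(axis=0) - 1.0) < 0.1)

    def test_empirical_frequency_within_binomial_bounds(self):
        n = 10_000
        cfg = SimulationConfig(n_individuals=n, n_variants=20, maf_range=(0.2, 0.2), seed=4)
        G = simulate_genotypes(cfg)
        freq = G.mean(axis=0) / 2
        bound = 3 * np.sqrt(0.2 * 0.8 / (2 * n))
        assert np.all(np.abs(freq - 0.2) < 4 * bound)  # 20 simultaneous variants

    def test_invalid_config_rejected(self):
        with pytest.raises(InputError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(InputError):
            SimulationConfig(genetic_variance=1.5)


class TestPhenotypes:
    def test_null_model_gives_unit_mean_chi2(self):
        cfg = SimulationConfig(
            n_individuals=1500, n_variants=400, n_phenotypes=2, n_covariates=2,
            genetic_variance=0.0, seed=8,
        )
        G = simulate_genotypes(cfg)
        X, Z, truth = simulate_phenotypes(G, cfg)
        assert np.all(truth["W"] == 0)
        _, _, t, _, _ = direct_scan(X[:, 0], G, Z)
        assert np.mean(t**2) == pytest.approx(1.0, abs=0.25)

    def test_uncorrelated_noise_gives_small_residual_correlations(self):
        cfg = SimulationConfig(
            n_individuals=3000, n_variants=20, n_phenotypes=4, n_covariates=0,
            genetic_variance=0.0, phenotype_correlation=0.0, seed=9,
        )
        G = simulate_genotypes(cfg)
        X, _, _ = simulate_phenotypes(G, cfg)
        corr = np.corrcoef(X, rowvar=False)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_causal_variant_chi2_matches_noncentrality(self):
        # one causal variant explaining 2% of variance at n=2000: E[chi2] ~ 1 + n*0.02
        chis = []
        for seed in range(30):
            cfg = SimulationConfig(
                n_individuals=2000, n_variants=5, n_phenotypes=1, n_covariates=0,
                genetic_variance=0.02, causal_per_phenotype=1,
                phenotype_correlation=0.0, seed=seed,
            )
            G = simulate_genotypes(cfg)
            X, Z, truth = simulate_phenotypes(G, cfg)
            causal = int(np.flatnonzero(truth["W"][:, 0])[0])
            _, _, t, _, _ = direct_scan(X[:, 0], G, Z)
            chis.append(t[causal] ** 2)
        assert np.mean(chis) == pytest.approx(41.0, abs=8.0)

    def test_binary_features_hit_target_prevalence(self):
        cfg = SimulationConfig(n_individuals=1000, n_variants=50, n_phenotypes=8, seed=10)
        G = simulate_genotypes(cfg)
        B, _, _ = simulate_binary_features(G, cfg, prevalence=0.05)
        assert set(np.unique(B.to_numpy())) <= {0.0, 1.0}
        np.testing.assert_allclose(B.mean(axis=0), 0.05, atol=0.002)


class TestProjectionsAndDefinitions:
    def test_projections_reproducible_and_normal(self):
        fids = [f"x{i}" for i in range(20)]
        a = random_projections(fids, 60, seed=5)
        b = random_projections(fids, 60, seed=5)
        assert all(np.array_equal(p.weights, q.weights) for p, q in zip(a, b))
        weights = np.concatenate([p.weights for p in a])  # 1200 draws
        assert sps.normaltest(weights).pvalue > 1e-3

    def test_identity_controls_included_on_request(self):
        fids = ["a", "b", "c"]
        projs = random_projections(fids, 2, seed=1, include_identity=True)
        assert len(projs) == 5
        np.testing.assert_array_equal(projs[0].weights, [1, 0, 0])

    def test_definitions_reproducible_and_template_balanced(self):
        fids = [f"c{i}" for i in range(10)]
        a = random_boolean_definitions(fids, 500, seed=2)
        b = random_boolean_definitions(fids, 500, seed=2)
        assert [d.to_json() for d in a] == [d.to_json() for d in b]
        # five templates, roughly uniform at large count
        def shape(d):
            return (d.op, tuple(c.op for c in d.children))
        counts = pd.Series([shape(d) for d in a]).value_counts()
        assert len(counts) == 5
        assert counts.min() > 500 / 5 * 0.6

    def test_or_of_disjoint_rare_codes_adds_prevalences(self):
        X = pd.DataFrame({"a": [1.0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                          "b": [0.0, 1, 1, 0, 0, 0, 0, 0, 0, 0]})
        from indirectgwas import parse_definition
        y = evaluate(parse_definition("a OR b"), X)
        assert y.mean() == pytest.approx(0.1 + 0.2)

    def test_self_contradictory_definition_is_constant(self):
        from indirectgwas import parse_definition
        X = pd.DataFrame({"a": [1.0, 0, 1]})
        y = evaluate(parse_definition("a AND (NOT a)"), X)
        assert np.ptp(y) == 0  # rejected downstream as zero-variance


class TestFidelityMetric:
    def test_identical_vectors_give_one(self):
        a = np.array([1.0, 4.0, 0.5, 9.0])
        assert gwas_fidelity(a, a) == pytest.approx(1.0)

    def test_negated_shifted_vector_gives_minus_one(self):
        a = np.array([1.0, 4.0, 0.5, 9.0])
        assert gwas_fidelity(a, -a + 100) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        b = np.array([2.0, 1.0, 5.0, 9.0, 12.0])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert gwas_fidelity(a, b) == pytest.approx(num / den, rel=1e-12)

    @pytest.mark.parametrize("a,b", [([1, 1, 1], [1, 2, 3]), ([1, 2], [1, 2])])
    def test_degenerate_inputs_rejected(self, a, b):
        with pytest.raises(InputError):
            gwas_fidelity(np.array(a, dtype=float), np.array(b, dtype=float))


class TestHarness:
    def test_direct_and_indirect_agree_on_small_cohort(self):
        cfg = SimulationConfig(
            n_individuals=400, n_variants=80, n_phenotypes=5, n_covariates=3, seed=13
        )
        report = validate_direct_vs_indirect(cfg, n_projections=10)
        assert report["max_rel_beta"] <= 1e-6
        assert report["max_rel_se"] <= 1e-6
        assert report["min_chi2_r2"] >= 1 - 1e-6

    def test_single_feature_projection_is_exact(self):
        cfg = SimulationConfig(
            n_individuals=300, n_variants=40, n_phenotypes=4, n_covariates=2, seed=14
        )
        p = Projection(cfg.phenotype_ids, np.eye(4)[1])
        report = validate_direct_vs_indirect(cfg, projections=[p])
        assert report["max_rel_beta"] <= 1e-10
        assert report["max_rel_se"] <= 1e-10


class TestPreprocessingUtilities:
    def test_inverse_rank_normal_is_standardish_normal(self, rng):
        x = rng.exponential(size=5000)
        z = inverse_rank_normal(x)
        assert sps.normaltest(z).pvalue > 1e-3
        assert np.mean(z) == pytest.approx(0.0, abs=0.05)
        # rank order preserved
        assert np.all(np.argsort(z) == np.argsort(x))

    def test_min_observation_filter_drops_rare_codes(self, rng):
        X = pd.DataFrame(
            {
                "common": (rng.random(500) < 0.5).astype(float),
                "rare": (rng.random(500) < 0.01).astype(float),
            }
        )
        kept = filter_min_observations(X, min_count=100)
        assert list(kept.columns) == ["common"]
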