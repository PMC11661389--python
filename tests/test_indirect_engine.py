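"""The indirect engine against hand algebra and the direct-GWAS oracle."""

import numpy as np
import pytest

from indirectgwas import (
    FeatureStatsBlock,
    InputError,
    PartialCovariance,
    Projection,
    direct_scan,
    estimate_genotype_variance,
    feature_stats_from_scan,
    indirect_coefficient,
    indirect_scan,
    indirect_stderr,
    min_sample_size,
    partial_covariance,
    residualize,
)


def _block_and_cov(small_cohort):
    cfg, G, X, Z, _ = small_cohort
    block = feature_stats_from_scan(X, G, Z, cfg.phenotype_ids, cfg.variant_ids)
    C = partial_covariance(X, Z, cfg.phenotype_ids)
    return cfg, G, X, Z, block, C


class TestGenotypeVariance:
    def test_algebraic_identity(self):
        # Var(x)=1, b=0, s=1/sqrt(d)  =>  Var(g~) = 1/(d * 1/d) = 1
        d = 25
        est = estimate_genotype_variance(np.array([0.0]), np.array([d**-0.5]), np.array([1.0]), d)
        assert est.pooled == pytest.approx(1.0, rel=1e-12)

    def test_hand_arithmetic(self):
        # 1 / (0.05^2 * 100 + 0.1^2) = 1/0.26
        est = estimate_genotype_variance(np.array([0.1]), np.array([0.05]), np.array([1.0]), 100)
        assert est.pooled == pytest.approx(1 / 0.26, rel=1e-12)

    def test_matches_raw_genotype_variance(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        Gr = residualize(G, Z)
        d = Gr.dof
        for j in [0, 10, 30]:
            est = estimate_genotype_variance(
                block.b[j], block.s[j], C.feature_variances, d
            )
            raw = Gr.values[:, j] @ Gr.values[:, j] / (cfg.n_individuals - 1)
            assert est.pooled == pytest.approx(raw, rel=1e-6)
            # with exact inputs every per-feature estimate agrees
            np.testing.assert_allclose(est.per_feature, raw, rtol=1e-6)

    def test_all_missing_rejected(self):
        with pytest.raises(InputError, match="missing"):
            estimate_genotype_variance(
                np.array([np.nan]), np.array([np.nan]), np.array([1.0]), 10
            )


class TestScalarOps:
    def test_identity_projection_returns_feature_coefficient(self):
        p = Projection(["a", "b", "c"], [0.0, 1.0, 0.0])
        assert indirect_coefficient(np.array([1.5, -2.0, 3.0]), p) == -2.0

    def test_zero_projection_rejected(self):
        with pytest.raises(InputError, match="nonzero"):
            Projection(["a", "b"], [0.0, 0.0])

    def test_alignment_is_by_id(self):
        p = Projection(["b", "a"], [1.0, 2.0])
        beta = indirect_coefficient(np.array([10.0, 20.0]), p, feature_ids=["a", "b"])
        assert beta == 20.0 * 1.0 + 10.0 * 2.0

    def test_unknown_feature_id_is_hard_error(self):
        p = Projection(["z"], [1.0])
        with pytest.raises(InputError, match="absent"):
            indirect_coefficient(np.array([1.0]), p, feature_ids=["a"])

    def test_stderr_round_trips_single_feature(self):
        # identity projection recovers the input standard error exactly
        d, var_x, b, s = 100, 1.0, 0.1, 0.05
        gvar = estimate_genotype_variance(np.array([b]), np.array([s]), np.array([var_x]), d)
        C = PartialCovariance(np.array([[var_x]]), ["a"], float(d))
        p = Projection(["a"], [1.0])
        se = indirect_stderr(p, C, gvar, b, d)
        assert se == pytest.approx(s, rel=1e-12)

    def test_inconsistent_inputs_yield_nan(self):
        C = PartialCovariance(np.array([[1.0]]), ["a"], 10.0)
        gvar = estimate_genotype_variance(np.array([0.0]), np.array([0.1]), np.array([1.0]), 10)
        se = indirect_stderr(Projection(["a"], [1.0]), C, gvar, beta=100.0, dof=10)
        assert np.isnan(se)

    @pytest.mark.parametrize(
        "n_row,weights,expected",
        [
            ([1000, 900, 800], [1.0, 1.0, 0.0], 900),
            ([700, 700, 700], [1.0, -2.0, 0.5], 700),
            ([5, 10**6, 10**6], [1.0, 1.0, 1.0], 5),
        ],
    )
    def test_min_sample_size(self, n_row, weights, expected):
        p = Projection(["a", "b", "c"], weights)
        assert min_sample_size(np.array(n_row, dtype=float), p) == expected


class TestIndirectScan:
    def test_identity_projection_round_trip(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        p = Projection(cfg.phenotype_ids, np.eye(len(cfg.phenotype_ids))[2])
        res = indirect_scan(block, C, p)
        np.testing.assert_allclose([r.beta for r in res], block.b[:, 2], rtol=1e-10)
        np.testing.assert_allclose([r.se for r in res], block.s[:, 2], rtol=1e-10)

    def test_chunk_size_invariance(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        p = Projection(cfg.phenotype_ids, np.arange(1.0, len(cfg.phenotype_ids) + 1))
        a = indirect_scan(block, C, p, chunk_size=1)
        b = indirect_scan(block, C, p, chunk_size=10_000)
        assert [(r.variant_id, r.beta, r.se, r.neg_log10_p) for r in a] == [
            (r.variant_id, r.beta, r.se, r.neg_log10_p) for r in b
        ]

    def test_matches_direct_gwas_for_arbitrary_projections(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        rng = np.random.default_rng(5)
        for w in [rng.standard_normal(6), np.array([1.0, -1, 0, 0, 2, 0])]:
            p = Projection(cfg.phenotype_ids, w)
            beta_d, se_d, t_d, _, _ = direct_scan(X @ w, G, Z)
            res = indirect_scan(block, C, p)
            np.testing.assert_allclose([r.beta for r in res], beta_d, rtol=1e-6)
            np.testing.assert_allclose([r.se for r in res], se_d, rtol=1e-6)
            np.testing.assert_allclose([r.t for r in res], t_d, rtol=1e-6)

    def test_t_invariant_under_projection_rescaling(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        w = np.arange(1.0, 7.0)
        r1 = indirect_scan(block, C, Projection(cfg.phenotype_ids, w))
        r2 = indirect_scan(block, C, Projection(cfg.phenotype_ids, 3.5 * w))
        r3 = indirect_scan(block, C, Projection(cfg.phenotype_ids, -w))
        np.testing.assert_allclose([r.t for r in r1], [r.t for r in r2], rtol=1e-10)
        np.testing.assert_allclose([r.beta for r in r2], [3.5 * r.beta for r in r1], rtol=1e-10)
        np.testing.assert_allclose([r.beta for r in r3], [-r.beta for r in r1], rtol=1e-10)
        np.testing.assert_allclose([r.se for r in r2], [3.5 * r.se for r in r1], rtol=1e-10)

    def test_shuffled_feature_order_gives_identical_results(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(cfg.phenotype_ids))
        shuffled = block.align_features([cfg.phenotype_ids[i] for i in perm])
        p = Projection(cfg.phenotype_ids, rng.standard_normal(6))
        a = indirect_scan(block, C, p)
        b = indirect_scan(shuffled, C, p)
        np.testing.assert_allclose([r.beta for r in a], [r.beta for r in b], atol=0)

    def test_missing_feature_policies(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        b = block.b.copy()
        s = block.s.copy()
        b[7, 0] = np.nan
        s[7, 0] = np.nan
        holey = FeatureStatsBlock(block.variant_ids, block.feature_ids, b, s, block.n)
        p = Projection(cfg.phenotype_ids, np.ones(6))
        dropped = indirect_scan(holey, C, p, missing_policy="drop")
        assert len(dropped) == block.n_variants - 1
        assert all(r.variant_id != block.variant_ids[7] for r in dropped)
        with pytest.warns(UserWarning, match="incomplete"):
            kept = indirect_scan(holey, C, p, missing_policy="available")
        assert len(kept) == block.n_variants

    def test_projection_intercept_ignored(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        w = np.arange(1.0, 7.0)
        a = indirect_scan(block, C, Projection(cfg.phenotype_ids, w, intercept=0.0))
        b = indirect_scan(block, C, Projection(cfg.phenotype_ids, w, intercept=12.5))
        np.testing.assert_allclose([r.beta for r in a], [r.beta for r in b], atol=0)

    def test_per_chromosome_covariance_hook(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        half = block.n_variants // 2
        chroms = ["1"] * half + ["2"] * (block.n_variants - half)
        mixed = FeatureStatsBlock(
            block.variant_ids, block.feature_ids, block.b, block.s, block.n, chroms
        )
        p = Projection(cfg.phenotype_ids, np.ones(6))
        per_chrom = indirect_scan(mixed, {"1": C, "2": C}, p)
        single = indirect_scan(mixed, C, p)
        np.testing.assert_allclose([r.beta for r in per_chrom], [r.beta for r in single], atol=0)
        with pytest.raises(InputError, match="chromosome"):
            indirect_scan(mixed, {"1": C}, p)

    def test_missing_covariate_metadata_rejected(self, small_cohort):
        cfg, G, X, Z, block, C = _block_and_cov(small_cohort)
        bare = PartialCovariance(C.values, C.feature_ids, C.divisor)
        with pytest.raises(InputError, match="covariate count"):
            indirect_scan(block, bare, Projection(cfg.phenotype_ids, np.ones(6)))
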