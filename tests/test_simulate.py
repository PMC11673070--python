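"""Tests of the synthetic cohort generator: LD structure, GWAS calibration,
phenotype variance decomposition and ultrasound rank-correlation targets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidprs as lp
from lipidprs.simulate import simulate_covariates


class TestGenotypes:
    def test_independent_variants_have_near_zero_correlation(self):
        spec = lp.LDBlockSpec(n_blocks=2, variants_per_block=5, within_block_r=0.0)
        g = lp.simulate_genotypes(2000, spec, seed=5)
        r = np.corrcoef(g.dosages, rowvar=False)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert off.mean() < 0.08

    def test_fixed_maf_half_gives_frequencies_near_half(self):
        spec = lp.LDBlockSpec(n_blocks=4, variants_per_block=5, maf_range=(0.5, 0.5))
        g = lp.simulate_genotypes(5000, spec, seed=6)
        freq = g.allele_freq()
        assert freq.min() >= 0.46 and freq.max() <= 0.54

    def test_within_block_correlation_increases_with_latent_r(self):
        def mean_block_r2(r):
            spec = lp.LDBlockSpec(n_blocks=10, variants_per_block=4, within_block_r=r)
            g = lp.simulate_genotypes(1500, spec, seed=7)
            vals = []
            for b in range(10):
                cols = g.variants.index[g.variants["block"] == b]
                rr = np.corrcoef(g.dosages[:, cols], rowvar=False)
                vals.append((rr[np.triu_indices_from(rr, k=1)] ** 2).mean())
            return np.mean(vals)

        assert mean_block_r2(0.2) < mean_block_r2(0.6) < mean_block_r2(0.9)

    def test_same_seed_is_bit_identical(self):
        spec = lp.LDBlockSpec(n_blocks=3, variants_per_block=4, missing_rate=0.05)
        a = lp.simulate_genotypes(50, spec, seed=9)
        b = lp.simulate_genotypes(50, spec, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_blocks": 0},
            {"within_block_r": 1.0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.3, 0.6)},
            {"missing_rate": 1.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lp.LDBlockSpec(**kwargs)


class TestBaseGwas:
    def test_null_gwas_is_calibrated(self):
        spec = lp.LDBlockSpec(n_blocks=200, variants_per_block=10, within_block_r=0.3)
        g = lp.simulate_genotypes(1000, spec, seed=21)
        ss = lp.simulate_base_gwas(g, np.zeros(g.n_variants), 100_000, seed=22)
        frac = (ss.table["pval"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_marginal_effect_converges_to_truth_without_ld(self):
        spec = lp.LDBlockSpec(n_blocks=40, variants_per_block=1, within_block_r=0.0)
        g = lp.simulate_genotypes(3000, spec, seed=23)
        eff = np.zeros(40)
        eff[7] = 0.1
        ss = lp.simulate_base_gwas(g, eff, 10_000_000, seed=24)
        freq = g.allele_freq()[7]
        beta_std = ss.table["beta"][7] * np.sqrt(2 * freq * (1 - freq))
        assert beta_std == pytest.approx(0.1, abs=0.01)

    def test_block_mates_of_causal_variant_reach_significance(self):
        spec = lp.LDBlockSpec(n_blocks=5, variants_per_block=10, within_block_r=0.9)
        g = lp.simulate_genotypes(2000, spec, seed=25)
        eff = np.zeros(g.n_variants)
        eff[3] = 0.1  # ~1% trait variance at standardized scale
        ss = lp.simulate_base_gwas(g, eff, 100_000, seed=26)
        mates = (g.variants["block"] == 0) & (np.arange(g.n_variants) != 3)
        assert (ss.table.loc[mates.to_numpy(), "pval"] < 1e-4).all()

    def test_monomorphic_variants_excluded_with_warning(self, tiny_genotypes):
        g = lp.GenotypeMatrix(
            tiny_genotypes.samples,
            tiny_genotypes.variants.copy(),
            np.column_stack([tiny_genotypes.dosages[:, :4], np.zeros(10)]),
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            ss = lp.simulate_base_gwas(g, np.zeros(5), 1000, seed=1)
        assert ss.n_variants == 4


class TestLipidPhenotypes:
    def test_zero_heritability_uncorrelates_score_and_phenotype(self):
        trait = lp.TraitSpec(h2=0.0, causal_fraction=0.1)
        g = lp.simulate_genotypes(2000, lp.LDBlockSpec(n_blocks=50, variants_per_block=5), seed=11)
        eff = lp.draw_effect_sizes(g.n_variants, 0.1, 0.5, seed=31)
        ph = lp.simulate_lipid_phenotypes(g, trait, seed=32, effects=eff)
        r = np.corrcoef(ph["genetic_liability"], ph["lipid"])[0, 1]
        assert abs(r) < 0.05

    def test_heritability_half_recovers_squared_correlation(self, block_genotypes):
        trait = lp.TraitSpec(h2=0.5, causal_fraction=0.1)
        g = lp.simulate_genotypes(2000, lp.LDBlockSpec(n_blocks=50, variants_per_block=5), seed=11)
        ph = lp.simulate_lipid_phenotypes(g, trait, seed=33)
        r2 = np.corrcoef(ph["genetic_liability"], ph["lipid"])[0, 1] ** 2
        assert 0.40 <= r2 <= 0.60

    def test_statin_effect_recovered_as_group_difference(self, block_genotypes):
        trait = lp.TraitSpec(
            h2=0.2, causal_fraction=0.1, mean=3.5, scale_sd=0.3,
            covariate_effects={"statin": -0.5},
        )
        g = lp.simulate_genotypes(4000, lp.LDBlockSpec(n_blocks=20, variants_per_block=5), seed=12)
        ph = lp.simulate_lipid_phenotypes(g, trait, seed=34, name="ldl")
        on = ph.loc[ph["statin"] == 1, "ldl"].mean()
        off = ph.loc[ph["statin"] == 0, "ldl"].mean()
        assert on - off == pytest.approx(-0.5, abs=0.1)

    def test_log_scale_trait_is_lognormal(self, block_genotypes):
        trait = lp.TraitSpec(h2=0.3, log_scale=True, mean=0.2, scale_sd=0.5)
        ph = lp.simulate_lipid_phenotypes(block_genotypes, trait, seed=35, name="tg")
        assert (ph["tg"] > 0).all()
        np.testing.assert_allclose(np.log(ph["tg"]), ph["log_tg"])

    def test_variance_decomposition_approaches_h2(self):
        g = lp.simulate_genotypes(
            5000, lp.LDBlockSpec(n_blocks=40, variants_per_block=5), seed=13
        )
        trait = lp.TraitSpec(h2=0.4, causal_fraction=0.2)
        ph = lp.simulate_lipid_phenotypes(g, trait, seed=36)
        resid = ph["lipid"] - ph["lipid"].mean()
        slope = np.polyfit(ph["genetic_liability"], resid, 1)[0]
        genetic_var = slope**2 * ph["genetic_liability"].var()
        assert genetic_var / resid.var() == pytest.approx(0.4, abs=0.05)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            lp.TraitSpec(h2=1.5)

    def test_covariate_marginals_match_design(self):
        cov = simulate_covariates(5000, seed=37)
        assert cov["age"].between(25, 67).all()
        assert cov["bmi"].between(16, 50).all()
        assert set(cov["smoking"].unique()) <= {0, 1, 2}
        assert cov["statin"].mean() == pytest.approx(0.05, abs=0.02)


class TestUltrasound:
    def test_target_rho_realized_within_band(self):
        rng = np.random.default_rng(41)
        liab = rng.standard_normal(1028)
        us = lp.simulate_ultrasound(liab, lp.UltrasoundSpec(target_rho=0.13), seed=42)
        rhos = [stats.spearmanr(liab, us[c]).statistic for c in us.columns]
        assert all(0.08 <= r <= 0.18 for r in rhos)

    def test_plaque_counts_are_nonnegative_integers(self):
        rng = np.random.default_rng(43)
        us = lp.simulate_ultrasound(
            rng.standard_normal(500), lp.UltrasoundSpec(target_rho=0.1), seed=44
        )
        for col in ("carotid_plaque_number", "femoral_plaque_number"):
            vals = us[col].to_numpy()
            assert (vals >= 0).all() and np.array_equal(vals, vals.round())

    def test_plaque_number_moments_match_spec(self):
        rng = np.random.default_rng(45)
        us = lp.simulate_ultrasound(
            rng.standard_normal(20_000), lp.UltrasoundSpec(target_rho=0.0), seed=46
        )
        assert us["carotid_plaque_number"].mean() == pytest.approx(1.51, abs=0.1)
        assert us["carotid_plaque_number"].std() == pytest.approx(1.56, abs=0.1)

    def test_marginal_bounds_hold(self):
        rng = np.random.default_rng(47)
        us = lp.simulate_ultrasound(
            rng.standard_normal(2000), lp.UltrasoundSpec(target_rho=0.15), seed=48
        )
        for territory in ("carotid", "femoral"):
            assert us[f"{territory}_max_stenosis"].between(0, 100).all()
            assert us[f"{territory}_total_stenosis"].between(0, 100).all()
            assert (us[f"{territory}_plaque_score"] >= 0).all()
            assert (us[f"{territory}_imt_right"] > 0).all()

    def test_out_of_range_rho_rejected(self):
        with pytest.raises(ValueError):
            lp.UltrasoundSpec(target_rho=0.5)

    def test_same_seed_is_bit_identical(self):
        rng = np.random.default_rng(49)
        liab = rng.standard_normal(300)
        a = lp.simulate_ultrasound(liab, lp.UltrasoundSpec(target_rho=0.1), seed=50)
        b = lp.simulate_ultrasound(liab, lp.UltrasoundSpec(target_rho=0.1), seed=50)
        pd.testing.assert_frame_equal(a, b)
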