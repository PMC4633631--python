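"""Univariate / multi-component REML behaviour and the liability transform."""
import numpy as np
import pytest

from coherit.errors import ComputationError, InsufficientDataError, ParameterError
from coherit.grm import build_grm, partition_snps
from coherit.reml import (LiabilityScaleParams, observed_to_liability,
                          partition_report, reml_fit)
from coherit.synthdata import SimParams, simulate_genotypes, simulate_liability_pair


def _sim(n, m, h2, seed, n_causal=None, **kw):
    p = SimParams(n_individuals=n, n_snps=m, n_causal=n_causal or max(m // 10, 10),
                  h2_trait1=h2, maf_range=(0.05, 0.5), prevalence1=0.5,
                  seed=seed, **kw)
    g = simulate_genotypes(p)
    eff, y1, _ = simulate_liability_pair(g, p)
    return g, eff, y1


class TestRemlFit:
    def test_null_phenotype_estimates_near_zero(self, rng):
        p = SimParams(n_individuals=1000, n_snps=2000, n_causal=0, seed=41)
        g = simulate_genotypes(p)
        y = rng.standard_normal(1000)
        fit = reml_fit(y, build_grm(g))
        assert fit.h2_obs <= 2 * fit.h2_obs_se + 1e-6

    def test_noiseless_genetic_phenotype_recovered(self):
        g, eff, _ = _sim(800, 1500, 1.0, seed=42)
        fit = reml_fit(eff.genetic1, build_grm(g))
        assert fit.h2_obs > 0.9

    def test_quantitative_recovery_with_se_coverage(self):
        hits = 0
        ests = []
        for rep in range(8):
            g, eff, _ = _sim(1000, 2000, 0.5, seed=500 + rep, n_causal=200)
            fit = reml_fit(eff.liability1, build_grm(g))
            ests.append(fit.h2_obs)
            if abs(fit.h2_obs - 0.5) <= 2 * fit.h2_obs_se:
                hits += 1
        assert np.mean(ests) == pytest.approx(0.5, abs=0.08)
        assert hits >= 6

    def test_sample_reordering_invariance(self):
        g, eff, _ = _sim(300, 600, 0.5, seed=44)
        fit = reml_fit(eff.liability1, build_grm(g))
        perm = np.random.default_rng(1).permutation(300)
        fit_p = reml_fit(eff.liability1[perm], build_grm(g.subset(samples=perm)))
        assert fit_p.h2_obs == pytest.approx(fit.h2_obs, abs=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-5)

    def test_two_component_mhc_share_recovered(self):
        p = SimParams(n_individuals=2000, n_snps=5000, n_causal=500,
                      h2_trait1=0.5, maf_range=(0.05, 0.5), prevalence1=0.5,
                      mhc_block=(0, 500), mhc_variance_share=0.3, seed=45)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        masks = partition_snps(g.snp_map)
        grm_mhc = build_grm(g, masks["MHC"], region="MHC")
        grm_rest = build_grm(g, masks["auto_exMHC"], region="auto_exMHC")
        fit = reml_fit(eff.liability1, [grm_rest, grm_mhc])
        total_g = fit.sigma_g.sum()
        share = fit.sigma_g[1] / total_g
        assert share == pytest.approx(0.3, abs=0.10)

    def test_min_samples_enforced(self, rng):
        p = SimParams(n_individuals=20, n_snps=50, n_causal=5, seed=46)
        g = simulate_genotypes(p)
        with pytest.raises(InsufficientDataError):
            reml_fit(rng.standard_normal(20), build_grm(g))

    def test_misaligned_grm_rejected(self, rng):
        g, eff, _ = _sim(200, 300, 0.5, seed=47)
        grm = build_grm(g)
        with pytest.raises(ParameterError):
            reml_fit(eff.liability1[:150], grm)

    def test_constant_phenotype_rejected(self):
        g, _, _ = _sim(200, 300, 0.5, seed=48)
        with pytest.raises(ComputationError):
            reml_fit(np.ones(200), build_grm(g))


class TestLiabilityTransform:
    def test_zero_maps_to_zero(self):
        for K, P in ((0.01, 0.5), (0.3, 0.1)):
            out = observed_to_liability(0.0, LiabilityScaleParams(K=K, P=P))
            assert out.h2 == 0.0

    def test_balanced_half_prevalence_multiplier_is_pi_over_two(self):
        params = LiabilityScaleParams(K=0.5, P=0.5)
        assert params.multiplier == pytest.approx(np.pi / 2, abs=1e-12)
        out = observed_to_liability(0.5, params)
        assert out.h2 == pytest.approx(0.25 * np.pi, abs=1e-12)

    def test_rare_disease_multiplier_oracle(self):
        # high-precision numeric evaluation of the closed form, frozen
        params = LiabilityScaleParams(K=0.005, P=0.1)
        assert params.multiplier == pytest.approx(1.3152930063668242, rel=1e-12)
        out = observed_to_liability(0.2, params, se=0.05)
        assert out.h2 == pytest.approx(0.2 * 1.3152930063668242, rel=1e-12)
        assert out.se == pytest.approx(0.05 * 1.3152930063668242, rel=1e-12)

    def test_exceeding_unity_warns_not_clamps(self):
        params = LiabilityScaleParams(K=0.5, P=0.5)
        with pytest.warns(UserWarning):
            out = observed_to_liability(0.9, params)
        assert out.exceeds_unity
        assert out.h2 > 1.0

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ParameterError):
            LiabilityScaleParams(K=0.0, P=0.5)


class TestPartitionReport:
    def test_printed_value_arithmetic(self):
        assert partition_report(0.454, 0.447)["pct_mhc"] == pytest.approx(
            1.5419, abs=1e-3)

    def test_equal_inputs_zero(self):
        assert partition_report(0.5, 0.5)["pct_mhc"] == 0.0

    def test_nonpositive_auto_undefined(self):
        assert np.isnan(partition_report(0.0, 0.1)["pct_mhc"])
        assert np.isnan(partition_report(-0.2, 0.1)["pct_mhc"])


def test_lrt_null_distribution_conservative():
    """Under no genetic signal the boundary-mixture p-values are
    stochastically >= uniform (small replicate check; the full 200-rep
    calibration lives in the acceptance suite)."""
    rng = np.random.default_rng(99)
    ps = []
    for rep in range(40):
        p = SimParams(n_individuals=300, n_snps=400, n_causal=0,
                      seed=2000 + rep)
        g = simulate_genotypes(p)
        y = rng.standard_normal(300)
        ps.append(reml_fit(y, build_grm(g)).lrt_p)
    ps = np.array(ps)
    for alpha in (0.1, 0.25, 0.5):
        assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 40)
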