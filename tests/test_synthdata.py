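"""Generator behaviour: reproducibility, allele-frequency targets,
liability structure, ascertainment, artifact injection, comorbid cases."""
import numpy as np
import pytest

from coherit.datatypes import MALE, MISSING
from coherit.errors import InsufficientDataError, ParameterError
from coherit.grm import build_grm
from coherit.synthdata import (SimParams, ascertain_case_control,
                               assign_comorbid_cases, inject_artifacts,
                               simulate_genotypes, simulate_liability_pair,
                               simulate_pair_study, simulate_study)


class TestSimulateGenotypes:
    def test_same_seed_bit_identical(self, small_params, small_geno):
        again = simulate_genotypes(small_params)
        assert np.array_equal(small_geno.dosage, again.dosage)

    def test_empirical_maf_respects_range(self):
        p = SimParams(n_individuals=2000, n_snps=300, maf_range=(0.05, 0.5),
                      n_causal=0, seed=1)
        g = simulate_genotypes(p)
        assert (g.maf() >= 0.01).all()

    def test_single_snp_frequency_within_binomial_error(self):
        n = 5000
        p = SimParams(n_individuals=n, n_snps=1, n_causal=0, seed=9)
        g = simulate_genotypes(p, freqs=[0.3])
        f = g.dosage.mean() / 2
        assert abs(f - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / (2 * n))

    def test_male_x_dosages_restricted(self, small_geno):
        male = small_geno.sex == MALE
        xcols = small_geno.is_x()
        sub = small_geno.dosage[np.ix_(male, np.flatnonzero(xcols))]
        assert set(np.unique(sub)) <= {0, 2}

    @pytest.mark.parametrize("bad", [
        dict(n_individuals=0), dict(n_snps=-5), dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.1, 0.6)), dict(rg_true=1.5),
        dict(n_causal=10_000), dict(prevalence1=0.0),
    ])
    def test_parameter_validation(self, bad):
        with pytest.raises(ParameterError):
            SimParams(**bad)


class TestLiabilityPair:
    def test_rg_one_gives_proportional_effects(self):
        p = SimParams(n_individuals=200, n_snps=100, n_causal=50,
                      h2_trait1=0.5, h2_trait2=0.5, rg_true=1.0, seed=2)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        np.testing.assert_allclose(eff.beta1, eff.beta2, atol=1e-12)

    def test_genetic_value_correlation_targets_rg(self):
        p = SimParams(n_individuals=20_000, n_snps=600, n_causal=500,
                      h2_trait1=0.5, h2_trait2=0.5, rg_true=0.66,
                      maf_range=(0.05, 0.5), seed=3)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        r = np.corrcoef(eff.genetic1, eff.genetic2)[0, 1]
        assert abs(r - 0.66) <= 0.05

    def test_case_count_matches_prevalence(self):
        n = 20_000
        p = SimParams(n_individuals=n, n_snps=200, n_causal=100,
                      h2_trait1=0.4, prevalence1=0.005, seed=4)
        g = simulate_genotypes(p)
        _, y1, _ = simulate_liability_pair(g, p)
        expected = n * 0.005
        assert abs(y1.sum() - expected) <= 3 * np.sqrt(n * 0.005 * 0.995)

    def test_mhc_block_variance_share(self):
        p = SimParams(n_individuals=4000, n_snps=400, n_causal=200,
                      h2_trait1=0.6, mhc_block=(0, 100), mhc_variance_share=0.4,
                      seed=5)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        in_blk = eff.causal_idx < 100
        var_blk = np.sum(eff.beta1[eff.causal_idx[in_blk]] ** 2)
        var_tot = np.sum(eff.beta1 ** 2)
        assert var_blk / var_tot == pytest.approx(0.4, abs=0.12)

    def test_exact_h2_pins_realized_effect_variance(self):
        p = SimParams(n_individuals=500, n_snps=200, n_causal=20,
                      h2_trait1=0.3, h2_trait2=0.5, rg_true=0.6,
                      exact_h2=True, seed=14)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        assert np.sum(eff.beta1 ** 2) == pytest.approx(0.3, rel=1e-12)
        assert np.sum(eff.beta2 ** 2) == pytest.approx(0.5, rel=1e-12)
        # scalar rescaling leaves the effect correlation structure intact
        c = eff.causal_idx
        r = np.corrcoef(eff.beta1[c], eff.beta2[c])[0, 1]
        assert r == pytest.approx(0.6, abs=0.25)

    def test_requires_complete_genotypes(self, small_geno, small_params):
        damaged = inject_artifacts(small_geno, missing_rate_per_snp=0.2, seed=1)
        with pytest.raises(ParameterError):
            simulate_liability_pair(damaged, small_params)


class TestAscertainment:
    def test_case_proportion_recorded(self, rng):
        y = rng.binomial(1, 0.3, 2000)
        s = ascertain_case_control(y, 100, 900, seed=0)
        assert s.case_proportion == pytest.approx(0.1)
        assert s.indices.size == 1000

    def test_zero_cases_rejected(self, rng):
        with pytest.raises(ParameterError):
            ascertain_case_control(rng.binomial(1, 0.3, 100), 0, 10, seed=0)

    def test_shortfall_reported(self):
        y = np.zeros(50)
        y[:5] = 1
        with pytest.raises(InsufficientDataError, match="shortfall"):
            ascertain_case_control(y, 10, 10, seed=0)

    def test_deterministic_under_seed(self, rng):
        y = rng.binomial(1, 0.3, 500)
        a = ascertain_case_control(y, 50, 200, seed=11)
        b = ascertain_case_control(y, 50, 200, seed=11)
        assert np.array_equal(a.indices, b.indices)


class TestInjectArtifacts:
    def test_missingness_hits_target_rate(self, small_geno):
        out = inject_artifacts(small_geno, missing_rate_per_snp=0.1, seed=3)
        cr = out.call_rate_snp()
        assert cr.mean() == pytest.approx(0.9, abs=0.02)

    def test_offspring_grm_near_half(self):
        p = SimParams(n_individuals=150, n_snps=2000, n_causal=0,
                      maf_range=(0.2, 0.5), seed=6)
        g = simulate_genotypes(p)
        out = inject_artifacts(g, n_related_pairs=2, seed=6)
        grm = build_grm(out)
        kid_rows = [i for i, iid in enumerate(out.sample_ids)
                    if iid.startswith("offspring")]
        for kid in kid_rows:
            top = np.sort(np.delete(grm.values[kid], kid))[-2:]
            assert np.all(np.abs(top - 0.5) < 0.12)

    def test_fst_zero_leaves_frequencies_alone(self, small_geno):
        out = inject_artifacts(small_geno, n_subpops=2, fst=0.0, seed=1)
        assert np.array_equal(out.dosage[: small_geno.n_samples],
                              small_geno.dosage)

    def test_differential_missingness_depends_on_status(self, small_geno):
        status = np.zeros(small_geno.n_samples, dtype=bool)
        status[:150] = True
        out = inject_artifacts(small_geno, differential_missing_snps=[5],
                               case_status=status, seed=2)
        miss = out.dosage[:, 5] == MISSING
        assert miss[:150].mean() > 0.1 and miss[150:].mean() == 0.0


class TestComorbidAssignment:
    def test_overlap_goes_to_smaller_cohort(self):
        sets = {"BIG": set(range(2000)), "SMALL": set(range(1900, 2000)) | {5}}
        out = assign_comorbid_cases(sets)
        assert 5 in out["SMALL"] and 5 not in out["BIG"]

    def test_no_overlap_identity(self):
        sets = {"A": {1, 2}, "B": {3, 4}}
        assert assign_comorbid_cases(sets) == sets

    def test_three_way_overlap_disjoint(self):
        sets = {"A": {1, 2, 9}, "B": {1, 3, 4, 9}, "C": {1, 5, 6, 7, 9}}
        out = assign_comorbid_cases(sets)
        all_members = sorted(x for s in out.values() for x in s)
        assert all_members == sorted(set(all_members))
        assert set().union(*out.values()) == {1, 2, 3, 4, 5, 6, 7, 9}


class TestAscertainedStudies:
    def test_single_trait_study_counts(self):
        p = SimParams(n_snps=300, n_causal=60, h2_trait1=0.5,
                      prevalence1=0.1, seed=8)
        st = simulate_study(p, 150, 350)
        assert st.geno.n_samples == 500
        assert st.y1.sum() == 150

    def test_pair_study_roles_disjoint(self):
        p = SimParams(n_snps=300, n_causal=60, h2_trait1=0.5, h2_trait2=0.5,
                      rg_true=0.5, prevalence1=0.15, prevalence2=0.15, seed=9)
        st = simulate_pair_study(p, 100, 100, 200)
        assert (st.roles == "case1").sum() == 100
        assert (st.roles == "case2").sum() == 100
        # controls are cases for neither trait
        ctrl = st.roles == "control"
        assert st.y1[ctrl].sum() == 0 and st.y2[ctrl].sum() == 0


def test_replicate_genetic_variance_calibration():
    """Across replicates at h2=0.5 the mean realized genetic variance
    stays within 2% of 0.5 (moment identity of the generator)."""
    vars_ = []
    for rep in range(200):
        p = SimParams(n_individuals=400, n_snps=120, n_causal=100,
                      h2_trait1=0.5, seed=1000 + rep)
        g = simulate_genotypes(p)
        eff, _, _ = simulate_liability_pair(g, p)
        vars_.append(eff.genetic1.var(ddof=1))
    assert np.mean(vars_) == pytest.approx(0.5, abs=0.01)
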