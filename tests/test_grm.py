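"""GRM against a brute-force oracle, region partition boundaries,
X-chromosome coding, relatedness pruning."""
import numpy as np
import pandas as pd
import pytest

from coherit.datatypes import (GenotypeData, make_sample_table, make_snp_map,
                               MISSING)
from coherit.errors import InsufficientDataError, ParameterError
from coherit.grm import (Grm, RegionSpec, build_grm, build_grm_x, combine_grms,
                         partition_snps, prune_related)
from coherit.synthdata import SimParams, simulate_genotypes


def brute_force_grm(dosage):
    """Double-loop reference implementation of the GRM formula."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    obs = dosage != MISSING
    x = np.where(obs, dosage, np.nan)
    f = np.nanmean(x, axis=0) / 2
    G = np.zeros((n, n))
    M = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            s = cnt = 0.0
            for i in range(m):
                if not (obs[j, i] and obs[k, i]):
                    continue
                if f[i] <= 0 or f[i] >= 1:
                    continue
                s += ((x[j, i] - 2 * f[i]) * (x[k, i] - 2 * f[i])
                      / (2 * f[i] * (1 - f[i])))
                cnt += 1
            G[j, k] = s / cnt if cnt else 0.0
            M[j, k] = cnt
    return G, M


def _geno(dosage, chrom=1, bp=1000, sex=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeData(dosage=dosage, snp_map=make_snp_map(m, chrom, bp),
                        sample_table=make_sample_table(n, sex=sex))


class TestBuildGrm:
    def test_single_snp_both_het_contributes_zero(self):
        g = _geno([[1], [1]])
        grm = build_grm(g)
        assert grm.values[0, 1] == pytest.approx(0.0)

    def test_single_snp_opposite_homs(self):
        # f = 0.5, dosages 2 and 0: (1)(-1)/0.5 = -2
        g = _geno([[2], [0]])
        grm = build_grm(g)
        assert grm.values[0, 1] == pytest.approx(-2.0)

    def test_matches_brute_force_with_missing(self, rng):
        dosage = rng.choice([0, 1, 2, MISSING], size=(5, 4),
                            p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        dosage[0, 0] = 1  # guarantee polymorphism of the first SNP
        g = _geno(dosage)
        grm = build_grm(g)
        ref_G, ref_M = brute_force_grm(dosage)
        np.testing.assert_allclose(grm.values, ref_G, atol=1e-10)
        np.testing.assert_allclose(grm.n_snps_used, ref_M, atol=0)

    def test_all_monomorphic_rejected(self):
        g = _geno(np.zeros((4, 3)))
        with pytest.raises(InsufficientDataError):
            build_grm(g)

    def test_unrelated_sample_moments(self):
        p = SimParams(n_individuals=500, n_snps=5000, maf_range=(0.05, 0.5),
                      n_causal=0, seed=17)
        g = simulate_genotypes(p)
        grm = build_grm(g)
        diag = np.diagonal(grm.values)
        off = grm.values[np.triu_indices(500, 1)]
        assert 0.98 <= diag.mean() <= 1.02
        assert -0.005 <= off.mean() <= 0.005
        assert off.std() == pytest.approx(1 / np.sqrt(5000), rel=0.2)

    def test_partition_weighted_recombination_identity(self, rng):
        dosage = rng.choice([0, 1, 2, MISSING], size=(30, 40),
                            p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        g = _geno(dosage)
        full = build_grm(g)
        part1 = build_grm(g, np.arange(15))
        part2 = build_grm(g, np.arange(15, 40))
        merged = combine_grms([part1, part2])
        np.testing.assert_allclose(merged.values, full.values, atol=1e-10)


class TestBuildGrmX:
    def test_all_female_reduces_to_autosomal(self, rng):
        dosage = rng.choice([0, 1, 2], size=(20, 10)).astype(np.int8)
        gx = _geno(dosage, chrom=23, sex=[2] * 20)
        ga = _geno(dosage, chrom=1, sex=[2] * 20)
        np.testing.assert_allclose(build_grm_x(gx).values,
                                   build_grm(ga).values, atol=1e-12)

    def test_male_coding_matches_oracle(self):
        """4-sample fixture, one SNP: hand-computed sex-aware scores."""
        dosage = np.array([[2], [0], [1], [2]], dtype=np.int8)
        sex = [1, 1, 2, 2]  # two males, two females
        g = _geno(dosage, chrom=23, sex=sex)
        grm = build_grm_x(g)
        # allele freq: males contribute 1+0, females 1+2 of (1+1+2+2)=6 alleles
        f = (1 + 0 + 1 + 2) / 6
        sd = np.sqrt(f * (1 - f))
        male = lambda a: np.sqrt(2) * (a - f) / sd
        female = lambda x: (x - 2 * f) / (np.sqrt(2) * sd)
        scores = np.array([male(1), male(0), female(1), female(2)])
        expected = np.outer(scores, scores)
        np.testing.assert_allclose(grm.values, expected, atol=1e-12)

    def test_no_x_snps_rejected(self, rng):
        g = _geno(rng.choice([0, 1, 2], size=(6, 4)), chrom=1, sex=[1, 2] * 3)
        with pytest.raises(InsufficientDataError):
            build_grm_x(g)

    def test_unknown_sex_rejected(self, rng):
        g = _geno(np.array([[0], [2]]), chrom=23, sex=[0, 2])
        with pytest.raises(ParameterError):
            build_grm_x(g)


class TestPartitionSnps:
    def test_boundaries_inside_mhc(self):
        snp_map = make_snp_map(4, [6, 6, 6, 6],
                               [26_499_999, 26_500_000, 34_000_000, 34_000_001])
        masks = partition_snps(snp_map)
        assert list(masks["MHC"]) == [False, True, True, False]
        assert list(masks["auto_exMHC"]) == [True, False, False, True]

    def test_fixture_counts(self):
        chroms = [1, 6, 6, 6, 6, 6, 12, 23, 23, 6]
        bps = [30_000_000, 1_000, 26_500_000, 30_000_000, 34_000_000,
               35_000_000, 5_000, 1_000, 2_000, 26_000_000]
        masks = partition_snps(make_snp_map(10, chroms, bps))
        assert masks["MHC"].sum() == 3
        assert masks["auto"].sum() == 8
        assert masks["auto_exMHC"].sum() == 5
        assert masks["X"].sum() == 2

    def test_invalid_region_rejected(self):
        with pytest.raises(ParameterError):
            RegionSpec(mhc_start=10, mhc_end=10)


class TestPruneRelated:
    def _grm(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        ids = np.array(ids if ids else [f"s{i}" for i in range(n)])
        return Grm(values=values, n_snps_used=np.full((n, n), 100.0),
                   region="auto", sample_ids=ids)

    def test_single_related_pair_one_removed(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.5
        kept = prune_related(self._grm(v))
        assert len(kept) == 2

    def test_chain_keeps_endpoints(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.3  # A-B
        v[1, 2] = v[2, 1] = 0.3  # B-C
        kept = prune_related(self._grm(v, ["A", "B", "C"]))
        assert sorted(kept) == ["A", "C"]

    def test_unrelated_all_retained(self):
        v = np.eye(4) + 0.01
        kept = prune_related(self._grm(v))
        assert len(kept) == 4
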