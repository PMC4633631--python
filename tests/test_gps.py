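"""GPS statistic, Z transform oracles, hypergeometric vs permutation."""
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coherit.errors import ComputationError, ParameterError
from coherit.gps import (adjusted_p_matrix, gps_all_pairs, gps_pvalue_analytic,
                         gps_pvalue_permutation, gps_statistic, gps_test,
                         pvalues_to_zscores)


def exhaustive_permutation_p(X, Y):
    """Exact permutation p by full enumeration (n! pairings)."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    gamma_obs = max(min(x, y) for x, y in zip(X, Y))
    count = total = 0
    for perm in permutations(range(len(Y))):
        g = max(min(x, Y[j]) for x, j in zip(X, perm))
        count += g >= gamma_obs
        total += 1
    return count / total


class TestZTransform:
    def test_p_one_maps_to_zero(self):
        assert pvalues_to_zscores([1.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantiles(self):
        z = pvalues_to_zscores([0.05, 5e-8])
        assert z[0] == pytest.approx(1.9599639845400545, rel=1e-10)
        assert z[1] == pytest.approx(5.451310437845478, rel=1e-10)

    def test_tiny_p_clipped(self):
        z = pvalues_to_zscores([1e-320])
        assert np.isfinite(z[0])
        assert z[0] == pytest.approx(37.0657878807, rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            pvalues_to_zscores([0.0, 0.5])


class TestStatistic:
    def test_identical_vectors_give_max(self, rng):
        x = rng.standard_normal(50)
        assert gps_statistic(x, x) == pytest.approx(x.max())

    def test_hand_enumeration(self):
        assert gps_statistic([3, 1, 2], [1, 4, 2]) == 2.0

    def test_single_pair(self):
        assert gps_statistic([1.7], [0.4]) == pytest.approx(0.4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            gps_statistic([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 9), st.floats(0.1, 5.0), st.integers(0, 1000))
    def test_monotone_in_any_single_score(self, pos, bump, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        g0 = gps_statistic(x, y)
        x2 = x.copy()
        x2[pos] += bump
        assert gps_statistic(x2, y) >= g0


class TestAnalyticP:
    def test_small_closed_forms(self):
        # n=3, a=b=1 -> 1/3; n=4, a=2, b=1 -> 1/2
        res = gps_pvalue_analytic(2.0, [2.0, 0.1, 0.2], [0.3, 2.0, 0.4])
        assert (res.a, res.b) == (1, 1)
        assert res.p_analytic == pytest.approx(1 / 3)
        res = gps_pvalue_analytic(2.0, [2.0, 2.5, 0.1, 0.2],
                                  [0.3, 2.0, 0.4, 0.5])
        assert (res.a, res.b) == (2, 1)
        assert res.p_analytic == pytest.approx(1 / 2)

    def test_saturated_exceedance_gives_one(self, rng):
        x = np.full(6, 3.0)
        y = rng.uniform(1, 2, 6)
        res = gps_test(x, y)
        assert res.p_analytic == pytest.approx(1.0)

    def test_zero_exceedance_is_internal_error(self):
        with pytest.raises(ComputationError):
            gps_pvalue_analytic(10.0, [1.0, 2.0], [1.0, 2.0])

    def test_equals_exhaustive_enumeration_small_n(self, rng):
        for trial in range(30):
            n = int(rng.integers(2, 7))
            x = np.round(rng.standard_normal(n), 2)
            y = np.round(rng.standard_normal(n), 2)
            res = gps_test(x, y)
            assert res.p_analytic == pytest.approx(
                exhaustive_permutation_p(x, y), abs=1e-12), (x, y)

    def test_equals_enumeration_with_ties(self):
        x = np.array([1.0, 1.0, 0.5, 2.0])
        y = np.array([2.0, 1.0, 1.0, 0.5])
        res = gps_test(x, y)
        assert res.p_analytic == pytest.approx(exhaustive_permutation_p(x, y))


class TestPermutationP:
    def test_agrees_with_analytic_null(self, rng):
        x = pvalues_to_zscores(rng.uniform(1e-6, 1, 500))
        y = pvalues_to_zscores(rng.uniform(1e-6, 1, 500))
        res = gps_test(x, y)
        p_perm = gps_pvalue_permutation(x, y, n_perm=4000, seed=5)
        se = np.sqrt(res.p_analytic * (1 - res.p_analytic) / 4000)
        assert abs(p_perm - res.p_analytic) <= 3 * se + 2 / 4000

    def test_constant_x_gives_p_one(self, rng):
        x = np.full(40, 1.5)
        y = rng.standard_normal(40)
        assert gps_pvalue_permutation(x, y, n_perm=200, seed=1) == 1.0

    def test_seed_determinism(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        a = gps_pvalue_permutation(x, y, n_perm=500, seed=9)
        b = gps_pvalue_permutation(x, y, n_perm=500, seed=9)
        assert a == b

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ParameterError):
            gps_pvalue_permutation(rng.standard_normal(5),
                                   rng.standard_normal(5), n_perm=10, seed=0)


class TestAllPairs:
    def _tables(self, n_cohorts, n_snps, rng):
        idx = pd.Index([f"rs{i}" for i in range(n_snps)], name="SNP")
        return {f"D{i}": pd.Series(rng.uniform(1e-6, 1, n_snps), index=idx)
                for i in range(n_cohorts)}

    def test_ten_cohorts_give_45_results(self, rng):
        tables = self._tables(10, 40, rng)
        out = gps_all_pairs(tables, exclude_mhc=False)
        assert len(out) == 45
        mat = adjusted_p_matrix(out)
        assert mat.shape == (10, 10)
        assert mat.notna().sum().sum() == 90

    def test_two_cohorts_one_result(self, rng):
        out = gps_all_pairs(self._tables(2, 30, rng), exclude_mhc=False)
        assert len(out) == 1

    def test_mismatched_universes_rejected(self, rng):
        tables = self._tables(2, 30, rng)
        tables["D1"] = tables["D1"].iloc[:-1]
        with pytest.raises(ParameterError, match="universes differ"):
            gps_all_pairs(tables, exclude_mhc=False)

    def test_shared_signal_ranks_above_null_pair(self, rng):
        idx = pd.Index([f"rs{i}" for i in range(2000)])
        base = {k: pd.Series(rng.uniform(1e-4, 1, 2000), index=idx)
                for k in ("A", "B", "C", "D")}
        shared = rng.choice(2000, 50, replace=False)
        for k in ("A", "B"):  # 50 strongly shared SNPs between A and B
            base[k].iloc[shared] = 10 ** -rng.uniform(6, 12, 50)
        out = gps_all_pairs(base, exclude_mhc=False).set_index(
            ["disease1", "disease2"])
        assert (out.loc[("A", "B"), "p_adj"]
                < out.loc[("C", "D"), "p_adj"])
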