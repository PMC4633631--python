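"""Genome-wide pairwise sharing (GPS) test.

A threshold-free test for the existence of SNPs associated with both of
two diseases.  Per-SNP association p-values are converted to two-sided
magnitude Z-scores, Z_j = Phi^-1(1 - p_j / 2), and the statistic is

    gamma = max_j min(X_j, Y_j)

over the n SNP-aligned score pairs.  Under the null that the pairing of
the two score vectors is exchangeable, the p-value has a closed
hypergeometric form: with a = #{X_j >= gamma} and b = #{Y_j >= gamma},

    p = 1 - C(n - a, b) / C(n, b),

the probability that a uniformly random re-pairing places at least one
large-X SNP against a large-Y SNP — so no actual permutation is required
(a permutation estimate is available as a cross-check).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .errors import ComputationError, ParameterError

#: Z-scores are clipped at the quantile of p = 1e-300.
P_FLOOR: float = 1e-300
Z_MAX: float = float(norm.isf(P_FLOOR / 2))


@dataclass
class GpsResult:
    gamma: float
    n: int
    a: int  # exceedance count on X
    b: int  # exceedance count on Y
    p_analytic: float
    p_permutation: float | None = None
    p_bonferroni: float | None = None


def pvalues_to_zscores(p_vector) -> np.ndarray:
    """Two-sided magnitude transform Z = Phi^-1(1 - p/2), clipped."""
    p = np.asarray(p_vector, dtype=np.float64)
    if (p <= 0).any():
        raise ParameterError("p-values must be in (0, 1]")
    if (p > 1).any():
        raise ParameterError("p-values must be in (0, 1]")
    return np.minimum(norm.isf(np.maximum(p, P_FLOOR) / 2.0), Z_MAX)


def gps_statistic(X, Y) -> float:
    """gamma = max over SNPs of the pairwise minimum of the two scores."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 1:
        raise ParameterError("X and Y must be SNP-aligned vectors of equal length")
    if X.size == 0:
        raise ParameterError("need at least one SNP")
    return float(np.max(np.minimum(X, Y)))


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def gps_pvalue_analytic(gamma: float, X, Y) -> GpsResult:
    """Hypergeometric p-value for an observed gamma (non-strict exceedance)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = X.size
    a = int((X >= gamma).sum())
    b = int((Y >= gamma).sum())
    if a == 0 or b == 0:
        raise ComputationError(
            "exceedance count of zero: gamma was not computed from these scores")
    if b > n - a:
        p = 1.0
    else:
        # p = 1 - C(n-a, b) / C(n, b), evaluated in log space
        logr = _log_choose(n - a, b) - _log_choose(n, b)
        p = float(-np.expm1(logr))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return GpsResult(gamma=float(gamma), n=n, a=a, b=b, p_analytic=p)


def gps_test(X, Y) -> GpsResult:
    """Statistic + analytic p in one call."""
    return gps_pvalue_analytic(gps_statistic(X, Y), X, Y)


def gps_pvalue_permutation(X, Y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo permutation p, permuting Y against X.

    p = (1 + #{gamma_perm >= gamma_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    gamma_obs = gps_statistic(X, Y)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7 // max(X.size, 1))))
    done = 0
    while done < n_perm:
        this = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(Y, (this, 1)), axis=1)
        gammas = np.minimum(X[None, :], perms).max(axis=1)
        exceed += int((gammas >= gamma_obs).sum())
        done += this
    return (1 + exceed) / (n_perm + 1)


def gps_all_pairs(pvalue_tables: dict, snp_map: pd.DataFrame | None = None,
                  exclude_mhc: bool = True, region=None) -> pd.DataFrame:
    """GPS test for every cohort pair with Bonferroni adjustment.

    ``pvalue_tables`` maps cohort name -> pandas Series of per-SNP
    p-values indexed by SNP id.  All cohorts must share one SNP universe.
    MHC SNPs are removed by default (``snp_map`` with chrom/bp columns
    required for that).  Returns a long-format table; the adjustment
    multiplies by the number of pairs tested (45 for 10 cohorts).
    """
    from .grm import RegionSpec, partition_snps

    names = sorted(pvalue_tables)
    if len(names) < 2:
        raise ParameterError("need at least two cohorts")
    universe = pvalue_tables[names[0]].index
    for nm in names[1:]:
        other = pvalue_tables[nm].index
        if not universe.equals(other):
            only_a = universe.difference(other)[:5].tolist()
            only_b = other.difference(universe)[:5].tolist()
            raise ParameterError(
                f"SNP universes differ between {names[0]} and {nm}; "
                f"first only in {names[0]}: {only_a}; first only in {nm}: {only_b}")
    keep = pd.Index(universe)
    if exclude_mhc:
        if snp_map is None:
            raise ParameterError("exclude_mhc requires a snp_map")
        masks = partition_snps(snp_map, region or RegionSpec())
        mhc_ids = set(snp_map.loc[masks["MHC"], "snp"])
        keep = keep[~keep.isin(mhc_ids)]
    n_pairs = len(names) * (len(names) - 1) // 2
    zs = {nm: pvalues_to_zscores(pvalue_tables[nm].loc[keep].to_numpy())
          for nm in names}
    rows = []
    for d1, d2 in combinations(names, 2):
        res = gps_test(zs[d1], zs[d2])
        rows.append({"disease1": d1, "disease2": d2, "gamma": res.gamma,
                     "n_snps": res.n, "a": res.a, "b": res.b,
                     "p": res.p_analytic,
                     "p_adj": min(1.0, n_pairs * res.p_analytic)})
    return pd.DataFrame(rows)


def adjusted_p_matrix(pairs: pd.DataFrame, names=None) -> pd.DataFrame:
    """Symmetric matrix of adjusted p-values (diagonal NaN)."""
    if names is None:
        names = sorted(set(pairs["disease1"]) | set(pairs["disease2"]))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for _, r in pairs.iterrows():
        mat.loc[r["disease1"], r["disease2"]] = r["p_adj"]
        mat.loc[r["disease2"], r["disease1"]] = r["p_adj"]
    return mat
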