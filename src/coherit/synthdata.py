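"""Synthetic genotypes and correlated liability-threshold phenotypes.

This module generates data with exactly the statistical structure the
downstream estimators assume: independent biallelic SNPs (optionally with
block-copied LD), additive causal effects drawn on *standardized* dosages
so that per-SNP explained variance is MAF-independent, a designated
extended-MHC block carrying a configurable share of the genetic variance,
a latent Gaussian liability with threshold ascertainment, and injectable
QC artifacts (missingness, differential missingness, HWE violations,
related individuals, two-way population structure).

Two correlated traits are simulated by drawing per-SNP effect pairs from a
bivariate normal with correlation ``rg_true``; an individual is a case for
trait *k* iff its liability exceeds the upper-``prevalence_k`` quantile of
the standard normal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    CHROM_X,
    FEMALE,
    MALE,
    MISSING,
    GenotypeData,
    make_sample_table,
    make_snp_map,
)
from .errors import InsufficientDataError, ParameterError
from .grm import RegionSpec


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for a pair of liability-threshold traits.

    ``mhc_block`` is a half-open SNP index range ``(start, stop)`` placed on
    chromosome 6 inside the extended MHC; ``mhc_variance_share`` is the
    fraction of each trait's genetic variance carried by causal SNPs inside
    that block.
    """

    n_individuals: int = 1000
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 200
    h2_trait1: float = 0.5
    h2_trait2: float = 0.5
    rg_true: float = 0.0
    prevalence1: float = 0.05
    prevalence2: float = 0.05
    mhc_block: tuple = (0, 0)  # half-open SNP index range
    mhc_variance_share: float = 0.0
    n_snps_x: int = 0
    ld_block: int = 1  # 1 = independent SNPs
    ld_r2: float = 0.8
    exact_h2: bool = False  # rescale effects so total genetic variance is exact
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ParameterError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ParameterError("n_causal must be in [0, n_snps]")
        if not -1.0 <= self.rg_true <= 1.0:
            raise ParameterError("|rg_true| must be <= 1")
        for h2 in (self.h2_trait1, self.h2_trait2):
            if not 0.0 <= h2 <= 1.0:
                raise ParameterError("heritabilities must be in [0, 1]")
        for K in (self.prevalence1, self.prevalence2):
            if not 0.0 < K < 1.0:
                raise ParameterError("prevalences must be in (0, 1)")
        s, e = self.mhc_block
        if not (0 <= s <= e <= self.n_snps):
            raise ParameterError("mhc_block must be a valid SNP index range")
        if not 0.0 <= self.mhc_variance_share <= 1.0:
            raise ParameterError("mhc_variance_share must be in [0, 1]")
        if self.n_snps_x < 0 or self.n_snps_x >= self.n_snps:
            raise ParameterError("n_snps_x must be in [0, n_snps)")


@dataclass
class TrueEffects:
    """Ground-truth effects and liabilities for a simulated trait pair."""

    beta1: np.ndarray  # per-SNP effects on standardized dosage, trait 1
    beta2: np.ndarray
    causal_idx: np.ndarray
    genetic1: np.ndarray  # per-individual genetic values
    genetic2: np.ndarray
    liability1: np.ndarray
    liability2: np.ndarray
    threshold1: float
    threshold2: float
    true_freqs: np.ndarray

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"snp_index": np.arange(len(self.beta1)),
             "beta1": self.beta1, "beta2": self.beta2,
             "causal": np.isin(np.arange(len(self.beta1)), self.causal_idx).astype(int)}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AscertainedSample:
    """Index subset from case-control ascertainment with its case fraction."""

    indices: np.ndarray
    n_cases: int
    n_controls: int

    @property
    def case_proportion(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


def _snp_layout(params: SimParams) -> pd.DataFrame:
    """Chromosome/position assignment: MHC block on chr6, X SNPs last."""
    n, (s, e), nx = params.n_snps, params.mhc_block, params.n_snps_x
    region = RegionSpec()
    chrom = np.empty(n, dtype=int)
    bp = np.empty(n, dtype=int)
    n_auto = n - nx
    # autosomal SNPs spread over chr1..22 at 10 kb spacing, MHC block remapped
    chrom[:n_auto] = 1 + (np.arange(n_auto) % 22)
    bp[:n_auto] = 1 + 10_000 * (np.arange(n_auto) // 22 + 1)
    if e > s:
        if e > n_auto:
            raise ParameterError("mhc_block must index autosomal SNPs")
        # keep chr6 sorted: block SNPs sit inside the MHC, remaining chr6
        # SNPs (which all have higher indices) are pushed above its end
        later6 = (chrom == region.mhc_chrom).copy()
        later6[:e] = False
        bp[later6] += region.mhc_end
        chrom[s:e] = region.mhc_chrom
        span = region.mhc_end - region.mhc_start
        bp[s:e] = region.mhc_start + (np.arange(e - s) * span) // max(e - s, 1)
    chrom[n_auto:] = CHROM_X
    bp[n_auto:] = 1 + 10_000 * np.arange(1, nx + 1)
    return make_snp_map(n, chrom, bp)


def simulate_genotypes(params: SimParams, freqs=None, sex=None) -> GenotypeData:
    """Draw genotypes binomially at allele frequencies uniform in maf_range.

    SNPs are independent unless ``params.ld_block > 1``, in which case each
    block of adjacent autosomal SNPs copies its first member with per-entry
    re-draw noise calibrated so adjacent pairs have r^2 ~ ``ld_r2``.
    Male X dosages are drawn as a single allele and stored as {0, 2}.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_individuals, params.n_snps
    if freqs is None:
        freqs = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)
    freqs = np.asarray(freqs, dtype=float)
    snp_map = _snp_layout(params)
    if sex is None:
        sex = rng.choice([MALE, FEMALE], size=n)
    dosage = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    if params.ld_block > 1:
        _apply_ld_blocks(dosage, freqs, params, rng)
    nx = params.n_snps_x
    if nx > 0:
        male = np.asarray(sex) == MALE
        xcols = slice(m - nx, m)
        alleles = rng.binomial(1, freqs[None, xcols], size=(int(male.sum()), nx))
        dosage[male, xcols] = (2 * alleles).astype(np.int8)
    sample_table = make_sample_table(n, sex=sex)
    return GenotypeData(dosage=dosage, snp_map=snp_map, sample_table=sample_table)


def _apply_ld_blocks(dosage, freqs, params: SimParams, rng) -> None:
    """Block-wise copying with flip noise: within a block every SNP copies
    the anchor, then each individual's genotype is independently re-drawn
    from Binomial(2, f) with probability eps = 1 - sqrt(ld_r2)."""
    m = params.n_snps - params.n_snps_x
    eps = 1.0 - np.sqrt(np.clip(params.ld_r2, 0.0, 1.0))
    for start in range(0, m, params.ld_block):
        stop = min(start + params.ld_block, m)
        for j in range(start + 1, stop):
            copy = dosage[:, start].copy()
            redraw = rng.random(dosage.shape[0]) < eps
            copy[redraw] = rng.binomial(2, freqs[j], size=int(redraw.sum()))
            dosage[:, j] = copy
            freqs[j] = freqs[start]


def _draw_effect_pairs(params: SimParams, causal_idx: np.ndarray, in_mhc: np.ndarray,
                       rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-causal-SNP effect pairs ~ BVN with correlation rg_true.

    Variances are set so trait k's genetic variance is h2_k, with the MHC
    block carrying ``mhc_variance_share`` of it when the block is in use.
    """
    nc = causal_idx.size
    base1 = np.full(nc, np.nan)
    base2 = np.full(nc, np.nan)
    n_in = int(in_mhc.sum())
    n_out = nc - n_in
    share = params.mhc_variance_share if n_in > 0 else 0.0
    for h2, out in ((params.h2_trait1, base1), (params.h2_trait2, base2)):
        if n_in > 0:
            out[in_mhc] = share * h2 / n_in
        if n_out > 0:
            out[~in_mhc] = (1.0 - share) * h2 / max(n_out, 1)
    u = rng.standard_normal(nc)
    v = rng.standard_normal(nc)
    rg = params.rg_true
    b1 = np.sqrt(base1) * u
    b2 = np.sqrt(base2) * (rg * u + np.sqrt(max(0.0, 1.0 - rg * rg)) * v)
    if params.exact_h2:
        # per-trait scalar rescaling: the realized sum of squared effects
        # hits the h2 target exactly instead of only in expectation
        # (chi-square fluctuation has relative SD sqrt(2/n_causal));
        # a scalar per trait leaves Corr(b1, b2) untouched
        for b, h2 in ((b1, params.h2_trait1), (b2, params.h2_trait2)):
            ss = float(np.sum(b * b))
            if ss > 0:
                b *= np.sqrt(h2 / ss)
    return b1, b2


def simulate_liability_pair(geno: GenotypeData, params: SimParams,
                            ) -> tuple[TrueEffects, np.ndarray, np.ndarray]:
    """Simulate two correlated case-control traits on complete genotypes.

    Causal SNPs are sampled from the non-X SNPs (preferring the MHC block to
    carry its configured variance share); effects act on dosages
    standardized with the *true* allele frequencies; residuals are
    independent N(0, 1 - h2); a sample is a case iff liability exceeds
    the upper-prevalence standard-normal quantile.
    """
    if (geno.dosage == MISSING).any():
        raise ParameterError("phenotype simulation requires complete genotypes "
                             "(inject missingness afterwards)")
    rng = np.random.default_rng(params.seed + 104729)
    n, m = geno.n_samples, geno.n_snps
    xmask = geno.is_x()
    eligible = np.flatnonzero(~xmask)
    if params.n_causal > eligible.size:
        raise ParameterError("n_causal exceeds the number of non-X SNPs")
    s, e = params.mhc_block
    block = np.arange(s, e)
    if block.size and params.mhc_variance_share > 0:
        # keep the block represented among causal SNPs
        n_blk = min(block.size, max(1, int(round(params.n_causal * block.size / eligible.size))))
        blk_pick = rng.choice(block, size=n_blk, replace=False)
        rest = np.setdiff1d(eligible, block)
        out_pick = rng.choice(rest, size=params.n_causal - n_blk, replace=False)
        causal_idx = np.sort(np.concatenate([blk_pick, out_pick]))
    else:
        causal_idx = np.sort(rng.choice(eligible, size=params.n_causal, replace=False))
    in_mhc = (causal_idx >= s) & (causal_idx < e)

    # standardize with empirical frequencies of the simulated cohort
    x = geno.dosage[:, causal_idx].astype(np.float64)
    f = x.mean(axis=0) / 2.0
    f = np.clip(f, 1e-6, 1 - 1e-6)
    z = (x - 2 * f[None, :]) / np.sqrt(2 * f * (1 - f))[None, :]

    b1c, b2c = _draw_effect_pairs(params, causal_idx, in_mhc, rng)
    g1 = z @ b1c
    g2 = z @ b2c
    e1 = rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - params.h2_trait1))
    e2 = rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - params.h2_trait2))
    l1, l2 = g1 + e1, g2 + e2
    t1 = norm.isf(params.prevalence1)
    t2 = norm.isf(params.prevalence2)
    y1 = (l1 > t1).astype(np.int8)
    y2 = (l2 > t2).astype(np.int8)
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    beta1[causal_idx] = b1c
    beta2[causal_idx] = b2c
    effects = TrueEffects(beta1=beta1, beta2=beta2, causal_idx=causal_idx,
                          genetic1=g1, genetic2=g2, liability1=l1, liability2=l2,
                          threshold1=t1, threshold2=t2, true_freqs=f)
    return effects, y1, y2


def ascertain_case_control(phenos: np.ndarray, n_cases: int, n_controls: int,
                           seed: int) -> AscertainedSample:
    """Random subset with exactly the requested case/control counts."""
    phenos = np.asarray(phenos)
    if n_cases <= 0 or n_controls <= 0:
        raise ParameterError("n_cases and n_controls must be positive")
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(phenos == 1)
    controls = np.flatnonzero(phenos == 0)
    if cases.size < n_cases:
        raise InsufficientDataError(
            f"requested {n_cases} cases but only {cases.size} available "
            f"(shortfall {n_cases - cases.size})")
    if controls.size < n_controls:
        raise InsufficientDataError(
            f"requested {n_controls} controls but only {controls.size} available "
            f"(shortfall {n_controls - controls.size})")
    pick = np.concatenate([
        rng.choice(cases, size=n_cases, replace=False),
        rng.choice(controls, size=n_controls, replace=False),
    ])
    return AscertainedSample(indices=np.sort(pick), n_cases=n_cases,
                             n_controls=n_controls)


def inject_artifacts(geno: GenotypeData, *, missing_rate_per_snp=0.0,
                     differential_missing_snps=(), case_status=None,
                     hwe_violation_snps=(), n_related_pairs=0,
                     n_subpops=1, fst=0.0, seed=0) -> GenotypeData:
    """Return a copy of ``geno`` with QC-relevant artifacts added.

    Order of operations: population structure (Balding-Nichols re-draw of
    allele frequencies per subpopulation), HWE violations (excess
    homozygosity, inbreeding F = 0.5), related individuals (offspring rows
    appended, built by Mendelian transmission from random parent pairs),
    then missingness (uniform per SNP, plus case-dependent missingness for
    the flagged SNPs).
    """
    if not 0.0 <= missing_rate_per_snp <= 1.0:
        raise ParameterError("missing_rate_per_snp must be in [0, 1]")
    if not 0.0 <= fst < 1.0:
        raise ParameterError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dosage = geno.dosage.copy()
    n, m = dosage.shape
    freqs = np.clip(geno.allele_freq(), 0.01, 0.99)
    sample_table = geno.sample_table.copy()

    if n_subpops > 1 and fst > 0.0:
        assignment = np.repeat(np.arange(n_subpops), int(np.ceil(n / n_subpops)))[:n]
        a = freqs * (1 - fst) / fst
        b = (1 - freqs) * (1 - fst) / fst
        for s in range(n_subpops):
            fsub = rng.beta(a, b)
            rows = np.flatnonzero(assignment == s)
            dosage[rows, :] = rng.binomial(2, fsub[None, :], size=(rows.size, m)).astype(np.int8)
        sample_table = sample_table.assign(subpop=assignment)

    for j in np.asarray(hwe_violation_snps, dtype=int).ravel():
        f = dosage[:, j][dosage[:, j] != MISSING].mean() / 2.0
        F = 0.5
        p_hom1 = f * f + F * f * (1 - f)
        p_het = 2 * f * (1 - f) * (1 - F)
        draw = rng.choice([2, 1, 0], size=n, p=[p_hom1, p_het, 1 - p_hom1 - p_het])
        dosage[:, j] = draw.astype(np.int8)

    if n_related_pairs > 0:
        parents = rng.choice(n, size=(n_related_pairs, 2), replace=False)
        kids = np.empty((n_related_pairs, m), dtype=np.int8)
        for k, (p1, p2) in enumerate(parents):
            for p, col in ((p1, 0), (p2, 1)):
                d = np.clip(dosage[p].astype(np.int16), 0, 2)
                transmitted = rng.binomial(1, d / 2.0)
                kids[k] = transmitted if col == 0 else kids[k] + transmitted
        dosage = np.vstack([dosage, kids])
        extra = make_sample_table(n_related_pairs, prefix="offspring")
        extra["sex"] = rng.choice([MALE, FEMALE], size=n_related_pairs)
        sample_table = pd.concat([sample_table, extra], ignore_index=True)
        n = dosage.shape[0]

    if missing_rate_per_snp > 0:
        mask = rng.random((n, m)) < missing_rate_per_snp
        dosage[mask] = MISSING
    diff = np.asarray(differential_missing_snps, dtype=int).ravel()
    if diff.size:
        if case_status is None:
            raise ParameterError("differential missingness requires case_status")
        status = np.zeros(n, dtype=bool)
        cs = np.asarray(case_status).astype(bool)
        status[: cs.size] = cs
        for j in diff:
            mask = status & (rng.random(n) < 0.25)
            dosage[mask, j] = MISSING

    return GenotypeData(dosage=dosage, snp_map=geno.snp_map.copy(),
                        sample_table=sample_table.reset_index(drop=True))


@dataclass
class StudyData:
    """An ascertained case-control study simulated from a large population.

    ``roles`` tags each retained individual as ``case1``, ``case2`` (pair
    studies only) or ``control``; ``y1``/``y2`` are the binary phenotypes of
    the retained individuals; ``genetic1``/``genetic2`` their true genetic
    values.  ``population_size`` is the latent population that was screened.
    """

    geno: GenotypeData
    roles: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    genetic1: np.ndarray
    genetic2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    causal_idx: np.ndarray
    population_size: int


def _population_genetics(params: SimParams, n_pop: int, rng):
    """Causal genotypes + liabilities for a latent population.

    Only causal columns are materialized at population scale; null SNPs are
    independent of the phenotype so they can be drawn later for the
    ascertained individuals only — the joint distribution is unchanged.
    """
    m = params.n_snps
    freqs = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)
    xmask = np.zeros(m, dtype=bool)
    if params.n_snps_x:
        xmask[m - params.n_snps_x:] = True
    eligible = np.flatnonzero(~xmask)
    s, e = params.mhc_block
    block = np.arange(s, e)
    if block.size and params.mhc_variance_share > 0:
        n_blk = min(block.size, max(1, int(round(params.n_causal * block.size / eligible.size))))
        blk_pick = rng.choice(block, size=n_blk, replace=False)
        rest = np.setdiff1d(eligible, block)
        out_pick = rng.choice(rest, size=params.n_causal - n_blk, replace=False)
        causal_idx = np.sort(np.concatenate([blk_pick, out_pick]))
    else:
        causal_idx = np.sort(rng.choice(eligible, size=params.n_causal, replace=False))
    in_mhc = (causal_idx >= s) & (causal_idx < e)
    b1, b2 = _draw_effect_pairs(params, causal_idx, in_mhc, rng)
    fc = freqs[causal_idx]
    sd = np.sqrt(2 * fc * (1 - fc))
    geno_causal = np.empty((n_pop, causal_idx.size), dtype=np.int8)
    g1 = np.zeros(n_pop)
    g2 = np.zeros(n_pop)
    for start in range(0, causal_idx.size, 128):  # chunked to bound temporaries
        stop = min(start + 128, causal_idx.size)
        chunk = rng.binomial(2, fc[None, start:stop], size=(n_pop, stop - start))
        geno_causal[:, start:stop] = chunk
        z = (chunk - 2 * fc[None, start:stop]) / sd[None, start:stop]
        g1 += z @ b1[start:stop]
        g2 += z @ b2[start:stop]
    l1 = g1 + rng.standard_normal(n_pop) * np.sqrt(max(0.0, 1 - params.h2_trait1))
    l2 = g2 + rng.standard_normal(n_pop) * np.sqrt(max(0.0, 1 - params.h2_trait2))
    y1 = l1 > norm.isf(params.prevalence1)
    y2 = l2 > norm.isf(params.prevalence2)
    return freqs, causal_idx, b1, b2, geno_causal, g1, g2, y1, y2


def _fill_study(params: SimParams, keep, freqs, causal_idx, geno_causal, rng):
    """Genotype matrix for the retained individuals (null SNPs drawn here)."""
    m = params.n_snps
    n = keep.size
    dosage = np.empty((n, m), dtype=np.int8)
    null_cols = np.setdiff1d(np.arange(m), causal_idx)
    dosage[:, causal_idx] = geno_causal[keep, :]
    dosage[:, null_cols] = rng.binomial(2, freqs[None, null_cols], size=(n, null_cols.size)).astype(np.int8)
    snp_map = _snp_layout(params)
    sex = rng.choice([MALE, FEMALE], size=n)
    if params.n_snps_x:
        male = sex == MALE
        xcols = np.arange(m - params.n_snps_x, m)
        alleles = rng.binomial(1, freqs[None, xcols], size=(int(male.sum()), xcols.size))
        dosage[np.ix_(male, xcols)] = (2 * alleles).astype(np.int8)
    return GenotypeData(dosage=dosage, snp_map=snp_map,
                        sample_table=make_sample_table(n, sex=sex))


def simulate_study(params: SimParams, n_cases: int, n_controls: int,
                   n_population: int | None = None) -> StudyData:
    """Single-trait ascertained case-control study (trait 1 of ``params``)."""
    rng = np.random.default_rng(params.seed)
    K = params.prevalence1
    n_pop = n_population or int(np.ceil(max(n_cases / K * 1.35 + 200,
                                            n_controls / (1 - K) * 1.1 + 200)))
    freqs, causal_idx, b1, b2, gc, g1, g2, y1, y2 = _population_genetics(params, n_pop, rng)
    cases = np.flatnonzero(y1)
    controls = np.flatnonzero(~y1)
    if cases.size < n_cases:
        raise InsufficientDataError(
            f"population of {n_pop} yielded {cases.size} cases, need {n_cases}")
    keep = np.concatenate([rng.choice(cases, n_cases, replace=False),
                           rng.choice(controls, n_controls, replace=False)])
    geno = _fill_study(params, keep, freqs, causal_idx, gc, rng)
    roles = np.array(["case1"] * n_cases + ["control"] * n_controls)
    geno.sample_table["phenotype"] = np.where(roles == "case1", 2, 1)
    return StudyData(geno=geno, roles=roles, y1=y1[keep].astype(np.int8),
                     y2=y2[keep].astype(np.int8), genetic1=g1[keep], genetic2=g2[keep],
                     beta1=b1, beta2=b2, causal_idx=causal_idx, population_size=n_pop)


def simulate_pair_study(params: SimParams, n_cases1: int, n_cases2: int,
                        n_controls: int, n_population: int | None = None) -> StudyData:
    """Two-trait study: disjoint case cohorts plus a shared control pool.

    Individuals qualifying as cases for both traits go to the smaller
    cohort (comorbid-assignment rule); controls are cases for neither.
    """
    rng = np.random.default_rng(params.seed)
    Kmin = min(params.prevalence1, params.prevalence2)
    n_pop = n_population or int(np.ceil(
        (n_cases1 + n_cases2) / Kmin * 0.85 + n_controls * 1.15 + 500))
    freqs, causal_idx, b1, b2, gc, g1, g2, y1, y2 = _population_genetics(params, n_pop, rng)
    sets = assign_comorbid_cases({"D1": set(np.flatnonzero(y1)),
                                  "D2": set(np.flatnonzero(y2))})
    cases1 = np.array(sorted(sets["D1"]), dtype=int)
    cases2 = np.array(sorted(sets["D2"]), dtype=int)
    controls = np.flatnonzero(~y1 & ~y2)
    for have, need, label in ((cases1.size, n_cases1, "trait-1 cases"),
                              (cases2.size, n_cases2, "trait-2 cases"),
                              (controls.size, n_controls, "controls")):
        if have < need:
            raise InsufficientDataError(
                f"population of {n_pop} yielded {have} {label}, need {need}")
    keep = np.concatenate([rng.choice(cases1, n_cases1, replace=False),
                           rng.choice(cases2, n_cases2, replace=False),
                           rng.choice(controls, n_controls, replace=False)])
    geno = _fill_study(params, keep, freqs, causal_idx, gc, rng)
    roles = np.array(["case1"] * n_cases1 + ["case2"] * n_cases2
                     + ["control"] * n_controls)
    geno.sample_table["phenotype"] = np.where(roles == "control", 1, 2)
    return StudyData(geno=geno, roles=roles, y1=y1[keep].astype(np.int8),
                     y2=y2[keep].astype(np.int8), genetic1=g1[keep], genetic2=g2[keep],
                     beta1=b1, beta2=b2, causal_idx=causal_idx, population_size=n_pop)


def assign_comorbid_cases(case_sets: dict) -> dict:
    """Resolve individuals in several case sets to a single cohort.

    Each overlapping individual goes to the smaller cohort by
    post-assignment size (ties to the lexicographically smaller disease
    code).  Solved by fixed-point iteration on the size vector.
    """
    codes = sorted(case_sets)
    membership = {}
    for code in codes:
        for ind in case_sets[code]:
            membership.setdefault(ind, []).append(code)
    assignment = {ind: min(opts, key=lambda c: (len(case_sets[c]), c))
                  for ind, opts in membership.items()}
    for _ in range(100):
        sizes = {c: 0 for c in codes}
        for c in assignment.values():
            sizes[c] += 1
        new = {ind: min(opts, key=lambda c: (sizes[c], c))
               for ind, opts in membership.items()}
        if new == assignment:
            break
        assignment = new
    out = {c: set() for c in codes}
    for ind, c in assignment.items():
        out[c].add(ind)
    return out
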