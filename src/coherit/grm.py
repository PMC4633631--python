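"""Genetic relationship matrices over SNP subsets and relatedness pruning.

The GRM entry for individuals *j*, *k* is the average over SNPs, non-missing
in both, of the product of their standardized dosages:

    A_jk = (1 / m_jk) * sum_i (x_ij - 2 f_i)(x_ik - 2 f_i) / (2 f_i (1 - f_i))

with f_i the sample allele-1 frequency.  Matrices are built for the whole
autosome, the autosome excluding the extended MHC (chr6:26.5-34 Mb), the MHC
alone, and the X chromosome (with its own sex-aware standardization).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CHROM_X, FEMALE, MALE, MISSING, GenotypeData
from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class RegionSpec:
    """Extended MHC boundaries (1-based, both endpoints inside the region)."""

    mhc_chrom: int = 6
    mhc_start: int = 26_500_000
    mhc_end: int = 34_000_000

    def __post_init__(self):
        if not self.mhc_start < self.mhc_end:
            raise ParameterError("region start must be < end")


@dataclass
class Grm:
    """Symmetric relationship matrix with per-pair SNP counts.

    Attributes
    ----------
    values : (n, n) float64 symmetric matrix.
    n_snps_used : (n, n) array of non-missing SNP counts per pair.
    region : free-text tag ("auto", "auto_exMHC", "MHC", "X", ...).
    sample_ids : individual identifiers aligned to the matrix rows.
    """

    values: np.ndarray
    n_snps_used: np.ndarray
    region: str
    sample_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def write_gcta(self, prefix: str) -> None:
        """Write GCTA-compatible ``<prefix>.grm.gz`` + ``<prefix>.grm.id``."""
        n = self.n
        with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
            for j in range(n):
                for k in range(j + 1):
                    fh.write(
                        f"{j + 1}\t{k + 1}\t{int(self.n_snps_used[j, k])}\t"
                        f"{self.values[j, k]:.10g}\n"
                    )
        with open(f"{prefix}.grm.id", "w") as fh:
            for iid in self.sample_ids:
                fh.write(f"{iid}\t{iid}\n")


def partition_snps(snp_map: pd.DataFrame, region: RegionSpec = RegionSpec()) -> dict:
    """Split SNPs into {auto, auto_exMHC, MHC, X} boolean masks.

    Both MHC boundary positions are inside the MHC subset.
    """
    chrom = np.asarray(snp_map["chrom"])
    bp = np.asarray(snp_map["bp"])
    xmask = chrom == CHROM_X
    auto = (~xmask) & (chrom >= 1) & (chrom <= 22)
    mhc = (
        (chrom == region.mhc_chrom)
        & (bp >= region.mhc_start)
        & (bp <= region.mhc_end)
    )
    return {
        "auto": auto,
        "auto_exMHC": auto & ~mhc,
        "MHC": mhc,
        "X": xmask,
    }


def _standardized_scores(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize autosomal dosages; returns (Z, mask, polymorphic)."""
    obs = dosage != MISSING
    x = np.where(obs, dosage, 0).astype(np.float64)
    with np.errstate(invalid="ignore"):
        f = x.sum(axis=0) / (2.0 * obs.sum(axis=0))
    poly = (f > 0) & (f < 1) & (obs.sum(axis=0) > 0)
    denom = np.sqrt(np.maximum(2.0 * f * (1.0 - f), 1e-300))
    z = (x - 2.0 * f[None, :]) / denom[None, :]
    z[~obs] = 0.0
    z[:, ~poly] = 0.0
    return z, obs & poly[None, :], poly


def build_grm(geno: GenotypeData, snp_subset=None, region: str = "auto") -> Grm:
    """GRM from the given SNP subset with autosomal standardization.

    ``snp_subset`` may be a boolean mask, integer positions, or None (all
    SNPs).  Allele frequencies come from the analysis cohort itself.
    Monomorphic SNPs are skipped and do not enter the per-pair counts.
    """
    if snp_subset is None:
        sub = np.arange(geno.n_snps)
    else:
        sub = np.asarray(snp_subset)
        if sub.dtype == bool:
            sub = np.flatnonzero(sub)
    if sub.size == 0:
        raise InsufficientDataError("empty SNP subset for GRM")
    dosage = geno.dosage[:, sub]
    z, mask, poly = _standardized_scores(dosage)
    if not poly.any():
        raise InsufficientDataError("all SNPs in the subset are monomorphic")
    values = z @ z.T
    n = dosage.shape[0]
    if (dosage == MISSING).any():
        maskf = mask.astype(np.float64)
        counts = maskf @ maskf.T
    else:  # complete data: every pair uses every polymorphic SNP
        counts = np.full((n, n), float(poly.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, values / np.maximum(counts, 1), 0.0)
    return Grm(values=values, n_snps_used=counts, region=region,
               sample_ids=geno.sample_ids.copy())


def build_grm_x(geno: GenotypeData) -> Grm:
    """X-chromosome GRM under full dosage compensation.

    Females are standardized exactly as on the autosomes.  Males are scored
    on their allele count a in {0, 1} (stored dosage / 2) as
    sqrt(2) * (a - f) / sqrt(f (1 - f)), so an all-female cohort reduces to
    the autosomal formula.  The allele frequency pools two alleles per
    female and one per male.
    """
    xidx = np.flatnonzero(geno.is_x())
    if xidx.size == 0:
        raise InsufficientDataError("no X-chromosome SNPs")
    sex = geno.sex
    if np.any((sex != MALE) & (sex != FEMALE)):
        raise ParameterError("sex must be known (1/2) for every sample in the X GRM")
    dosage = geno.dosage[:, xidx]
    obs = dosage != MISSING
    male = sex == MALE
    x = np.where(obs, dosage, 0).astype(np.float64)
    a = x.copy()
    a[male, :] /= 2.0  # male allele count on the 0/1 scale
    alleles = 2.0 * obs.astype(np.float64)
    alleles[male, :] = obs[male, :].astype(np.float64)
    with np.errstate(invalid="ignore"):
        f = a.sum(axis=0) / alleles.sum(axis=0)
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise InsufficientDataError("all X SNPs are monomorphic")
    sd = np.sqrt(np.maximum(f * (1.0 - f), 1e-300))
    z = np.empty_like(x)
    z[~male, :] = (x[~male, :] - 2.0 * f[None, :]) / (np.sqrt(2.0) * sd[None, :])
    z[male, :] = np.sqrt(2.0) * (a[male, :] - f[None, :]) / sd[None, :]
    z[~obs] = 0.0
    z[:, ~poly] = 0.0
    maskf = (obs & poly[None, :]).astype(np.float64)
    counts = maskf @ maskf.T
    values = z @ z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, values / np.maximum(counts, 1), 0.0)
    return Grm(values=values, n_snps_used=counts, region="X",
               sample_ids=geno.sample_ids.copy())


def combine_grms(grms: list[Grm], region: str = "combined") -> Grm:
    """SNP-count-weighted combination of GRMs over disjoint SNP subsets."""
    total_counts = sum(g.n_snps_used for g in grms)
    num = sum(g.values * g.n_snps_used for g in grms)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total_counts > 0, num / np.maximum(total_counts, 1), 0.0)
    return Grm(values=values, n_snps_used=total_counts, region=region,
               sample_ids=grms[0].sample_ids.copy())


def prune_related(grm: Grm, threshold: float = 0.05, call_rate=None) -> np.ndarray:
    """Greedy maximum-retention relatedness pruning.

    Repeatedly removes the individual involved in the most over-threshold
    pairs (ties broken by lower call rate, then lexicographically larger
    identifier) until no off-diagonal entry exceeds ``threshold``.
    Returns the retained sample identifiers.
    """
    n = grm.n
    adj = grm.values > threshold
    np.fill_diagonal(adj, False)
    adj = adj | adj.T
    active = np.ones(n, dtype=bool)
    cr = np.ones(n) if call_rate is None else np.asarray(call_rate, dtype=float)
    ids = np.asarray(grm.sample_ids, dtype=str)
    degree = adj.sum(axis=1).astype(int)
    while True:
        if not (degree[active] > 0).any():
            break
        cand = np.flatnonzero(active & (degree == degree[active].max()))
        # tie-break: lower call rate first, then lexicographically later id
        order = sorted(cand, key=lambda i: (cr[i], tuple(-ord(c) for c in ids[i])))
        drop = order[0]
        active[drop] = False
        degree[adj[drop]] -= 1
        degree[drop] = 0
        adj[drop, :] = False
        adj[:, drop] = False
    return grm.sample_ids[active]
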