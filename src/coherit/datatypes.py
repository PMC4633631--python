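"""Core in-memory containers shared by all analysis stages.

Genotypes are held as an individuals x SNPs matrix of allele-1 dosages
(0, 1, 2) with ``MISSING`` (-1) marking no-calls, alongside a SNP map and a
sample table (pandas DataFrames mirroring the PLINK BIM/FAM columns).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Sentinel for a missing genotype call in the int8 dosage matrix.
MISSING: int = -1

#: PLINK sex codes.
MALE, FEMALE = 1, 2

#: Integer chromosome code used for the X chromosome.
CHROM_X: int = 23

SNP_COLUMNS = ["snp", "chrom", "bp", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "sex", "phenotype"]


@dataclass
class GenotypeData:
    """Dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosage:
        ``(n_samples, n_snps)`` int8 array of allele-1 counts; ``MISSING``
        (-1) marks a failed call.  On the X chromosome male dosages are
        restricted to ``{0, 2, MISSING}`` (hemizygous calls stored on the
        diploid scale).
    snp_map:
        One row per SNP with columns ``snp, chrom, bp, a1, a2`` (1-based
        physical positions; chromosomes as integers, X = 23).
    sample_table:
        One row per individual with columns ``fid, iid, sex, phenotype``
        (PLINK conventions: sex 1 = male / 2 = female / 0 = unknown,
        phenotype 1 = control / 2 = case / -9 = missing).
    """

    dosage: np.ndarray
    snp_map: pd.DataFrame
    sample_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ParameterError("dosage must be a 2-D individuals x SNPs matrix")
        if len(self.snp_map) != self.dosage.shape[1]:
            raise ParameterError(
                f"snp_map has {len(self.snp_map)} rows but dosage has "
                f"{self.dosage.shape[1]} columns"
            )
        if len(self.sample_table) != self.dosage.shape[0]:
            raise ParameterError(
                f"sample_table has {len(self.sample_table)} rows but dosage has "
                f"{self.dosage.shape[0]} rows"
            )
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.sample_table = self.sample_table.reset_index(drop=True)

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.sample_table["iid"].to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.sample_table["sex"].to_numpy()

    def is_x(self) -> np.ndarray:
        """Boolean mask over SNPs on the X chromosome."""
        return (self.snp_map["chrom"].to_numpy() == CHROM_X)

    # -- derived quantities --------------------------------------------------
    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with missing calls as NaN."""
        x = self.dosage.astype(np.float64)
        x[self.dosage == MISSING] = np.nan
        return x

    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - (self.dosage == MISSING).mean(axis=0)

    def call_rate_sample(self) -> np.ndarray:
        return 1.0 - (self.dosage == MISSING).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of allele 1 per SNP.

        On the X chromosome males contribute a single allele; elsewhere each
        non-missing genotype contributes two.
        """
        obs = self.dosage != MISSING
        dos = np.where(obs, self.dosage, 0).astype(np.float64)
        male = self.sex == MALE
        xmask = self.is_x()
        # allele counts: autosomes and female X count dosage/2 alleles of 2
        alleles = 2.0 * obs.astype(np.float64)
        counts = dos.copy()
        if xmask.any() and male.any():
            sub = np.ix_(male, np.flatnonzero(xmask))
            alleles[sub] = obs[sub].astype(np.float64)
            counts[sub] = dos[sub] / 2.0
        denom = alleles.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts.sum(axis=0) / denom
        return f

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    # -- subsetting ----------------------------------------------------------
    def subset(self, samples=None, snps=None) -> "GenotypeData":
        """Return a copy restricted to the given sample / SNP index arrays.

        Index arrays may be boolean masks or integer positions.
        """
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return GenotypeData(
            dosage=self.dosage[np.ix_(si, vi)].copy(),
            snp_map=self.snp_map.iloc[vi].reset_index(drop=True),
            sample_table=self.sample_table.iloc[si].reset_index(drop=True),
        )

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Positions of the given SNP identifiers (order preserved)."""
        lookup = pd.Index(self.snp_map["snp"])
        idx = lookup.get_indexer(np.asarray(snp_ids))
        if (idx < 0).any():
            missing = np.asarray(snp_ids)[idx < 0][:5]
            raise ParameterError(f"unknown SNP ids (first few): {list(missing)}")
        return idx

    def validate(self) -> None:
        """Check dosage-value invariants; raise ParameterError on violation."""
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ParameterError("dosage values must be in {0,1,2,missing}")
        male = self.sex == MALE
        xmask = self.is_x()
        if male.any() and xmask.any():
            sub = self.dosage[np.ix_(male, np.flatnonzero(xmask))]
            if np.isin(sub, [1]).any():
                raise ParameterError("male X dosages must be in {0,2,missing}")


def make_snp_map(n_snps: int, chrom, bp, a1="A", a2="G", prefix="snp") -> pd.DataFrame:
    """Convenience builder for a SNP map with generated identifiers."""
    return pd.DataFrame(
        {
            "snp": [f"{prefix}{i}" for i in range(n_snps)],
            "chrom": np.broadcast_to(np.asarray(chrom), (n_snps,)).copy(),
            "bp": np.broadcast_to(np.asarray(bp), (n_snps,)).copy(),
            "a1": a1 if np.ndim(a1) else [a1] * n_snps,
            "a2": a2 if np.ndim(a2) else [a2] * n_snps,
        }
    )


def make_sample_table(n: int, sex=None, phenotype=None, prefix="ind") -> pd.DataFrame:
    """Convenience builder for a sample table with generated identifiers."""
    ids = [f"{prefix}{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "fid": ids,
            "iid": ids,
            "sex": np.full(n, 0, dtype=int) if sex is None else np.asarray(sex, dtype=int),
            "phenotype": (
                np.full(n, -9, dtype=int)
                if phenotype is None
                else np.asarray(phenotype, dtype=int)
            ),
        }
    )
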