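"""Bit-exact PLINK 1 binary fileset (BED/BIM/FAM) reading and writing.

Only the SNP-major orientation (third magic byte 0x01) is supported.  Each
SNP occupies ceil(n_individuals / 4) bytes; the 2-bit codes, taken from the
low bits of each byte upward, are

    00 = homozygous allele 1 (dosage 2, allele 1 is the counted allele)
    01 = missing
    10 = heterozygous (dosage 1)
    11 = homozygous allele 2 (dosage 0)

Padding bits beyond the last individual are written as zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeData
from .errors import FormatError, TruncationError

MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage (allele-1 count); -1 marks missing
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass(frozen=True)
class PlinkFileset:
    """Paths of a .bed/.bim/.fam triple sharing one prefix."""

    bed: Path
    bim: Path
    fam: Path

    @classmethod
    def from_prefix(cls, prefix) -> "PlinkFileset":
        prefix = str(prefix)
        return cls(bed=Path(prefix + ".bed"), bim=Path(prefix + ".bim"),
                   fam=Path(prefix + ".fam"))


def _chrom_to_int(c) -> int:
    s = str(c).upper()
    if s in ("X", "23"):
        return 23
    return int(s)


def read_plink(fileset) -> GenotypeData:
    """Decode a PLINK binary fileset into a :class:`GenotypeData`.

    Dosage is the count of allele 1 (BIM column 5).  1-based BIM positions
    are retained.
    """
    if not isinstance(fileset, PlinkFileset):
        fileset = PlinkFileset.from_prefix(fileset)
    for path in (fileset.bed, fileset.bim, fileset.fam):
        if not Path(path).exists():
            raise FormatError(f"missing PLINK file: {path}")
    bim = pd.read_csv(fileset.bim, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"],
                      dtype={"snp": str, "a1": str, "a2": str})
    fam = pd.read_csv(fileset.fam, sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "phenotype"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    raw = Path(fileset.bed).read_bytes()
    if len(raw) < 3 or raw[:2] != MAGIC[:2]:
        raise FormatError(f"{fileset.bed}: bad BED magic bytes")
    if raw[2] != 0x01:
        raise FormatError(f"{fileset.bed}: only SNP-major BED (third byte 0x01) is supported")
    bps = (n + 3) // 4  # bytes per SNP
    expected = 3 + bps * m
    if len(raw) != expected:
        raise TruncationError(
            f"{fileset.bed}: expected {expected} bytes for {n} individuals x {m} SNPs, "
            f"found {len(raw)}")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bps)
    codes = np.empty((m, bps * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # -> individuals x SNPs
    snp_map = pd.DataFrame({
        "snp": bim["snp"], "chrom": bim["chrom"].map(_chrom_to_int),
        "bp": bim["bp"].astype(int), "a1": bim["a1"], "a2": bim["a2"],
    })
    sample_table = fam[["fid", "iid", "sex", "phenotype"]].copy()
    sample_table["sex"] = sample_table["sex"].astype(int)
    return GenotypeData(dosage=np.ascontiguousarray(dosage), snp_map=snp_map,
                        sample_table=sample_table)


def write_plink(geno: GenotypeData, prefix) -> PlinkFileset:
    """Write ``geno`` as a PLINK binary fileset; returns the paths."""
    fileset = PlinkFileset.from_prefix(prefix)
    n, m = geno.n_samples, geno.n_snps
    bps = (n + 3) // 4
    # dosage -> 2-bit codes; pad with code 00 (zero bits)
    lut = np.zeros(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        lut[d & 0xFF] = c  # missing (-1) wraps to byte 255
    codes = lut[geno.dosage.T.astype(np.uint8)]  # m x n
    padded = np.zeros((m, bps * 4), dtype=np.uint8)
    padded[:, :n] = codes
    body = np.zeros((m, bps), dtype=np.uint8)
    for shift in range(4):
        body |= padded[:, shift::4] << (2 * shift)
    try:
        with open(fileset.bed, "wb") as fh:
            fh.write(MAGIC)
            fh.write(body.tobytes())
        bim = pd.DataFrame({
            "chrom": geno.snp_map["chrom"], "snp": geno.snp_map["snp"], "cm": 0,
            "bp": geno.snp_map["bp"], "a1": geno.snp_map["a1"], "a2": geno.snp_map["a2"],
        })
        bim.to_csv(fileset.bim, sep="\t", header=False, index=False)
        fam = pd.DataFrame({
            "fid": geno.sample_table["fid"], "iid": geno.sample_table["iid"],
            "pid": 0, "mid": 0, "sex": geno.sample_table["sex"],
            "phenotype": geno.sample_table["phenotype"],
        })
        fam.to_csv(fileset.fam, sep="\t", header=False, index=False)
    except OSError as exc:
        raise FormatError(f"failed writing PLINK fileset at prefix {prefix}: {exc}") from exc
    return fileset


def read_table(path) -> pd.DataFrame:
    """Whitespace-delimited phenotype/covariate table with FID IID header."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    cols = [c.upper() for c in df.columns[:2]]
    if cols != ["FID", "IID"]:
        raise FormatError(f"{path}: first two columns must be FID IID, found {list(df.columns[:2])}")
    return df


def intersect_snp_ids(*id_lists) -> np.ndarray:
    """SNP identifiers present in every list, in the order of the first."""
    if not id_lists:
        return np.array([], dtype=str)
    keep = set(id_lists[0])
    for ids in id_lists[1:]:
        keep &= set(ids)
    first = np.asarray(id_lists[0])
    return first[np.isin(first, list(keep))]
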