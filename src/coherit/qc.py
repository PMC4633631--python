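"""SNP- and sample-level quality control filters.

Filters follow standard case-control GWAS practice: SNPs failing call rate
(< 0.95), minor allele frequency (< 0.01), Hardy-Weinberg equilibrium in
controls (exact test, P < 0.01) or case/control differential missingness
(two-sided Fisher exact, P < 1e-3 by default) are removed, in that order,
with per-stage counts logged.  Samples are filtered on mean call rate.
X-chromosome SNPs use females only for HWE (males are hemizygous) and the
sex-aware allele frequency for MAF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datatypes import FEMALE, MISSING, GenotypeData
from .errors import InsufficientDataError, ParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.01
    diff_missing_p_min: float = 1e-3
    sample_call_rate_min: float = 0.95

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-stage removal counts plus the surviving identifiers."""

    stage_removed: dict = field(default_factory=dict)
    n_input: int = 0
    retained_ids: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_removed(self) -> int:
        return sum(self.stage_removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": k, "removed": v} for k, v in self.stage_removed.items()]
        rows.append({"stage": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_exact_test(hom1: int, het: int, hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  An
    all-zero or monomorphic configuration returns 1 by convention.
    """
    if min(hom1, het, hom2) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = hom1 + het + hom2
    if n == 0:
        return 1.0
    rare = 2 * min(hom1, hom2) + het  # minor allele count
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, rare) up to a constant:
    #   n! / (a! h! b!) * 2^h  with a = (rare - h)/2 minor homs, b = n - a - h
    from scipy.special import gammaln
    a = (rare - hets) // 2
    b = n - a - hets
    logp = (-gammaln(a + 1.0) - gammaln(hets + 1.0) - gammaln(b + 1.0)
            + hets * np.log(2.0))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.flatnonzero(hets == het)[0]]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    return (int((column == 2).sum()), int((column == 1).sum()),
            int((column == 0).sum()))


def filter_snps(geno: GenotypeData, case_status, thresholds: QcThresholds = QcThresholds(),
                ) -> tuple[QcReport, GenotypeData]:
    """Apply the SNP filters in order; returns (report, filtered data).

    ``case_status`` is a boolean/0-1 vector aligned to the samples; HWE is
    computed in controls only and differential missingness contrasts
    missing-call counts in cases vs controls.
    """
    status = np.asarray(case_status).astype(bool)
    if status.size != geno.n_samples:
        raise ParameterError("case_status must align with samples")
    report = QcReport(n_input=geno.n_snps)
    keep = np.ones(geno.n_snps, dtype=bool)
    is_x = geno.is_x()
    female = geno.sex == FEMALE

    cr = geno.call_rate_snp()
    fail = keep & (cr < thresholds.snp_call_rate_min)
    report.stage_removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    maf = geno.maf()
    fail = keep & ((maf < thresholds.maf_min) | ~np.isfinite(maf))
    report.stage_removed["maf"] = int(fail.sum())
    keep &= ~fail

    controls = ~status
    n_hwe_fail = 0
    for j in np.flatnonzero(keep):
        rows = controls & female if is_x[j] else controls
        col = geno.dosage[rows, j]
        col = col[col != MISSING]
        p = hwe_exact_test(*_genotype_counts(col))
        if p < thresholds.hwe_p_min:
            keep[j] = False
            n_hwe_fail += 1
    report.stage_removed["hwe"] = n_hwe_fail

    n_dm_fail = 0
    miss = geno.dosage == MISSING
    n_cases, n_controls = int(status.sum()), int((~status).sum())
    for j in np.flatnonzero(keep):
        mc = int(miss[status, j].sum())
        mu = int(miss[~status, j].sum())
        if mc + mu == 0:
            continue
        table = [[mc, n_cases - mc], [mu, n_controls - mu]]
        _, p = fisher_exact(table, alternative="two-sided")
        if p < thresholds.diff_missing_p_min:
            keep[j] = False
            n_dm_fail += 1
    report.stage_removed["differential_missingness"] = n_dm_fail

    if not keep.any():
        raise InsufficientDataError("no SNPs survive QC")
    report.retained_ids = geno.snp_ids[keep]
    for stage, cnt in report.stage_removed.items():
        log.info("SNP QC stage %-26s removed %d", stage, cnt)
    log.info("SNP QC retained %d of %d", report.n_retained, report.n_input)
    return report, geno.subset(snps=keep)


def filter_samples(geno: GenotypeData, thresholds: QcThresholds = QcThresholds(),
                   ) -> tuple[QcReport, GenotypeData]:
    """Remove samples with mean call rate below threshold."""
    report = QcReport(n_input=geno.n_samples)
    cr = geno.call_rate_sample()
    keep = cr >= thresholds.sample_call_rate_min
    report.stage_removed["call_rate"] = int((~keep).sum())
    if not keep.any():
        raise InsufficientDataError("no samples survive QC")
    report.retained_ids = geno.sample_ids[keep]
    log.info("sample QC retained %d of %d", report.n_retained, report.n_input)
    return report, geno.subset(samples=keep)
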