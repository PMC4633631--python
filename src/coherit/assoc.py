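"""Per-SNP logistic-regression GWAS with covariates and genomic control.

Each SNP is tested in an additive logistic model (0/1/2 minor-allele
dosage) with optional covariates (conventionally sex plus the top 10
ancestry PCs), reporting the Wald log-odds effect, standard error,
chi-square and p-value.  The genomic inflation factor lambda_GC is the
median association chi-square divided by the chi-square(1df) median.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .datatypes import MISSING, GenotypeData
from .errors import InsufficientDataError, ParameterError

#: Median of the 1-df chi-square distribution, to full precision.
CHI2_MEDIAN_1DF: float = float(chi2.ppf(0.5, 1))


@dataclass
class AssocResult:
    """Per-SNP summary statistics plus the cohort's genomic inflation."""

    table: pd.DataFrame  # SNP CHR BP A1 BETA SE CHISQ P FLAG
    lambda_gc: float

    def pvalues(self) -> pd.Series:
        return self.table.set_index("SNP")["P"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _logistic_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 30,
                     tol: float = 1e-8):
    """Newton/IRLS logistic fit; returns (beta, se, converged, separated)."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    dev_old = np.inf
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False, True
        # step-halving on deviance increase
        for _ in range(12):
            cand = beta + step
            mu_c = expit(X @ cand)
            mu_c = np.clip(mu_c, 1e-12, 1 - 1e-12)
            dev = -2 * np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c))
            if dev <= dev_old + 1e-10:
                break
            step *= 0.5
        beta = cand
        if abs(dev_old - dev) < tol * (abs(dev) + 1):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    separated = bool(np.abs(beta).max() > 15) or not np.all(np.isfinite(se))
    return beta, se, converged, separated


def gwas_logistic(geno: GenotypeData, case_status, covariates=None) -> AssocResult:
    """Additive logistic GWAS over all SNPs.

    Dosages are oriented to the cohort minor allele before regression.
    Missing genotypes are dropped casewise per SNP.  Non-convergent,
    separated or constant SNPs are flagged with ``P`` missing rather than
    failing the scan.
    """
    y = np.asarray(case_status, dtype=float)
    if y.size != geno.n_samples:
        raise ParameterError("case_status must align with samples")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != geno.n_samples:
            raise ParameterError("covariates must align with samples")
    n, m = geno.n_samples, geno.n_snps
    freqs = geno.allele_freq()
    flip = freqs > 0.5

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    flag = np.zeros(m, dtype=object)
    flag[:] = ""
    p_cov = 0 if covariates is None else covariates.shape[1]
    for j in range(m):
        col = geno.dosage[:, j].astype(np.float64)
        obs = geno.dosage[:, j] != MISSING
        g = col[obs]
        if flip[j]:
            g = 2.0 - g
        if np.all(g == g[0]):
            flag[j] = "constant"
            continue
        yj = y[obs]
        if covariates is None:
            X = np.column_stack([np.ones(g.size), g])
        else:
            X = np.column_stack([np.ones(g.size), covariates[obs], g])
        b, s, conv, sep = _logistic_newton(X, yj)
        if not conv:
            flag[j] = "nonconvergent"
            continue
        if sep:
            flag[j] = "separated"
            continue
        beta[j] = b[-1]
        se[j] = s[-1]

    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = (beta / se) ** 2
        pvals = chi2.sf(chisq, 1)
    ok = np.isfinite(chisq)
    lam = lambda_gc(chisq[ok]) if ok.any() else np.nan
    a1 = np.where(flip, geno.snp_map["a2"], geno.snp_map["a1"])
    table = pd.DataFrame({
        "SNP": geno.snp_ids, "CHR": geno.snp_map["chrom"],
        "BP": geno.snp_map["bp"], "A1": a1, "BETA": beta, "SE": se,
        "CHISQ": chisq, "P": pvals, "FLAG": flag.astype(str),
    })
    return AssocResult(table=table, lambda_gc=lam)


def lambda_gc(chi_squares) -> float:
    """Genomic inflation: median chi-square over the chi2(1) median."""
    arr = np.asarray(chi_squares, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise InsufficientDataError("lambda_GC needs at least one chi-square statistic")
    return float(np.median(arr) / CHI2_MEDIAN_1DF)
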