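"""SNP-heritability estimation by AI-REML and the liability-scale transform.

The observed-scale model is y = X beta + sum_c g_c + e with
g_c ~ N(0, A_c sigma_c^2) for one or more genetic relationship matrices
A_c (all autosomes, autosomes excluding the extended MHC, MHC only, ChrX).
SNP-h^2 on the observed scale is sum_c sigma_c^2 / (sum_c sigma_c^2 +
sigma_e^2); for an ascertained case-control sample with population
prevalence K and sample case proportion P it is transformed to the
liability scale by

    h2_liab = h2_obs * K^2 (1 - K)^2 / (P (1 - P) z^2),   z = phi(Phi^-1(1 - K)),

the standard case-control ascertainment correction; the same multiplier is
applied to the standard error (delta method with K, P treated as fixed).
Significance of the genetic variance uses a likelihood-ratio test against
the no-genetics model with the boundary null mixture 1/2 chi2(0) + 1/2
chi2(1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._varcomp import (DenseComponent, DiagonalComponent,
                       fit_variance_components, reml_null_loglik)
from .errors import InsufficientDataError, ParameterError
from .grm import Grm


@dataclass(frozen=True)
class LiabilityScaleParams:
    """Population prevalence K and sample case proportion P."""

    K: float
    P: float

    def __post_init__(self):
        if not (0.0 < self.K < 1.0 and 0.0 < self.P < 1.0):
            raise ParameterError("K and P must be in (0, 1)")

    @property
    def threshold(self) -> float:
        return float(norm.isf(self.K))

    @property
    def density_at_threshold(self) -> float:
        return float(norm.pdf(self.threshold))

    @property
    def multiplier(self) -> float:
        z = self.density_at_threshold
        return (self.K ** 2 * (1 - self.K) ** 2) / (self.P * (1 - self.P) * z ** 2)


@dataclass
class LiabilityEstimate:
    h2: float
    se: float
    multiplier: float
    exceeds_unity: bool = False


@dataclass
class RemlFit:
    """Variance components and derived heritability of one REML fit."""

    varcomp: np.ndarray  # genetic variances, then residual (observed scale)
    varcomp_se: np.ndarray
    varcomp_cov: np.ndarray
    component_names: list
    h2_obs: float
    h2_obs_se: float
    component_shares: np.ndarray  # each sigma_c^2 / total phenotypic variance
    loglik: float
    loglik_null: float
    lrt_p: float
    n_iter: int
    converged: bool
    n_samples: int

    @property
    def sigma_g(self) -> np.ndarray:
        return self.varcomp[:-1]

    @property
    def sigma_e(self) -> float:
        return float(self.varcomp[-1])


def _h2_and_se(theta: np.ndarray, cov: np.ndarray) -> tuple[float, float, np.ndarray]:
    total = theta.sum()
    S = theta[:-1].sum()
    h2 = S / total
    # gradient of S/T wrt each component (T includes the residual)
    grad = np.empty_like(theta)
    grad[:-1] = (total - S) / total ** 2
    grad[-1] = -S / total ** 2
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    shares = theta / total
    return float(h2), se, shares


def reml_fit(y, grms, covariates=None, *, tol=1e-6, max_iter=100,
             min_samples=50) -> RemlFit:
    """Fit one or more genetic variance components to a phenotype.

    Parameters
    ----------
    y : 0/1 (or quantitative) phenotype vector.
    grms : a single :class:`Grm` or a list of them, sample-aligned with y.
    covariates : optional n x p matrix (an intercept is added internally;
        conventionally the top 20 ancestry PCs).
    """
    if isinstance(grms, Grm):
        grms = [grms]
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < min_samples:
        raise InsufficientDataError(f"need at least {min_samples} samples, got {n}")
    for g in grms:
        if g.values.shape != (n, n):
            raise ParameterError(f"GRM '{g.region}' is not aligned with the phenotype")
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        X = np.column_stack([np.ones(n), covariates])

    components = [DenseComponent(g.values) for g in grms]
    components.append(DiagonalComponent(np.ones(n)))
    names = [f"V({g.region})" for g in grms] + ["V(e)"]
    fit = fit_variance_components(y, X, components, names, tol=tol,
                                  max_iter=max_iter)
    h2, h2_se, shares = _h2_and_se(fit.theta, fit.cov)
    logl0 = reml_null_loglik(y, X)
    lrt = 2.0 * (fit.loglik - logl0)
    k = len(grms)
    if k == 1:
        # boundary mixture 1/2 point-mass(0) + 1/2 chi2(1)
        p = 0.5 * chi2.sf(max(lrt, 0.0), 1) + (0.5 if lrt <= 0 else 0.0)
    else:
        p = float(chi2.sf(max(lrt, 0.0), k))
    return RemlFit(varcomp=fit.theta, varcomp_se=fit.se, varcomp_cov=fit.cov,
                   component_names=names, h2_obs=h2, h2_obs_se=h2_se,
                   component_shares=shares, loglik=fit.loglik,
                   loglik_null=logl0, lrt_p=float(min(p, 1.0)),
                   n_iter=fit.n_iter, converged=fit.converged, n_samples=n)


def observed_to_liability(h2_obs: float, params: LiabilityScaleParams,
                          se: float | None = None) -> LiabilityEstimate:
    """Transform an observed-scale estimate to the liability scale.

    A value above 1 is reported unclamped with ``exceeds_unity`` set (and a
    warning), since clamping would hide estimator behaviour.
    """
    mult = params.multiplier
    h2_liab = h2_obs * mult
    se_liab = (se * mult) if se is not None else np.nan
    exceeds = bool(h2_liab > 1.0)
    if exceeds:
        warnings.warn(f"liability-scale h2 = {h2_liab:.3f} exceeds 1; "
                      "reported unclamped", stacklevel=2)
    return LiabilityEstimate(h2=float(h2_liab), se=float(se_liab),
                             multiplier=float(mult), exceeds_unity=exceeds)


def partition_report(h2_auto: float, h2_exmhc: float,
                     joint_shares: dict | None = None) -> dict:
    """Percentage of autosomal SNP-h^2 attributable to the extended MHC.

    %MHC = 100 (h2_auto - h2_exMHC) / h2_auto; undefined (NaN) when the
    autosomal estimate is non-positive.  ``joint_shares`` (e.g. exMHC /
    MHC / X / residual shares from a joint fit) are passed through.
    """
    if h2_auto is None or not np.isfinite(h2_auto) or h2_auto <= 0:
        pct = float("nan")
    else:
        pct = 100.0 * (h2_auto - h2_exmhc) / h2_auto
    out = {"h2_auto": h2_auto, "h2_exMHC": h2_exmhc, "pct_mhc": pct}
    if joint_shares:
        out["joint_shares"] = dict(joint_shares)
    return out


def univariate_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-disease report (h2 per region, SEs, P, %MHC)."""
    cols = ["disease", "h2_auto", "se_auto", "p_auto", "h2_exMHC", "se_exMHC",
            "p_exMHC", "pct_mhc", "h2_X", "se_X", "p_X"]
    return pd.DataFrame(rows, columns=cols)
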