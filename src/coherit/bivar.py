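"""Bivariate REML: genetic correlation between two case-control cohorts.

Two disjoint cohorts (cases of disease 1 + half the pooled controls;
cases of disease 2 + the other half) are stacked into one mixed model

    [y1; y2] = X beta + [g1; g2] + [e1; e2]

where the genetic values have covariance

    Cov(g1, g1') = sigma_g1^2 A11,  Cov(g2, g2') = sigma_g2^2 A22,
    Cov(g1, g2') = sigma_g12 A12,

with A the genetic relationship matrix over the combined samples, and the
residual covariance is structurally zero (no individual appears on both
sides).  The genetic correlation rG = sigma_g12 / sqrt(sigma_g1^2
sigma_g2^2) is reported with a delta-method SE, and rG = 0 is tested by a
likelihood ratio against the model with the covariance fixed at zero
(chi-square with 1 df; the null is interior, not on a boundary).  rG is
invariant under linear rescaling of either phenotype, which is why the
observed-scale estimate doubles as the liability-scale estimate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._varcomp import DiagonalComponent, fit_variance_components
from .errors import InsufficientDataError, ParameterError
from .grm import Grm
from .reml import reml_fit


@dataclass
class PairDesign:
    """Control allocation for one disease pair (even random split)."""

    controls_side1: np.ndarray
    controls_side2: np.ndarray
    seed: int


@dataclass
class BivarFit:
    sigma_g1: float
    sigma_g2: float
    sigma_g12: float
    sigma_e1: float
    sigma_e2: float
    se: dict
    rg: float
    rg_se: float
    loglik: float
    loglik_null: float
    lrt_p: float
    n_iter: int
    converged: bool
    rg_missing_reason: str | None = None


def split_controls(control_ids, seed: int) -> PairDesign:
    """Evenly allocate pooled controls to the two sides, reproducibly.

    With an odd count the larger half goes to side 1.
    """
    ids = np.asarray(control_ids)
    if ids.size < 2:
        raise InsufficientDataError("need at least 2 controls to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    n1 = (ids.size + 1) // 2
    return PairDesign(controls_side1=np.sort(ids[perm[:n1]]),
                      controls_side2=np.sort(ids[perm[n1:]]),
                      seed=seed)


class _DiagBlock:
    """Genetic variance component confined to one cohort's diagonal block.

    Samples are sorted so the cohort occupies the contiguous index range
    [lo, hi).  Only the lower triangle of V is maintained — the Cholesky
    factorization and the masked traces never read the upper triangle.
    """

    def __init__(self, block: np.ndarray, lo: int, hi: int, n: int):
        self.block = np.ascontiguousarray(block)
        self.lo, self.hi, self.n = lo, hi, n
        self._low = np.tril(self.block, -1)
        self._diag = np.ascontiguousarray(np.diagonal(self.block))

    def add_to(self, V, coef):
        V[self.lo:self.hi, self.lo:self.hi] += coef * self.block

    def matmat(self, B):
        out = np.zeros((self.n,) + B.shape[1:])
        out[self.lo:self.hi] = self.block @ B[self.lo:self.hi]
        return out

    def trace_against(self, vi_lower):
        sub = vi_lower[self.lo:self.hi, self.lo:self.hi]
        return float(2.0 * np.einsum("ij,ij->", sub, self._low)
                     + np.dot(np.diagonal(sub), self._diag))


class _CrossBlock:
    """Genetic covariance component: the off-diagonal cohort-pair blocks.

    Holds the lower block B21 = A[n1:, :n1]; the symmetric counterpart is
    implied.  dV/d(sigma_g12) has both off-diagonal blocks, but only the
    lower one is written into V.
    """

    def __init__(self, b21: np.ndarray, n1: int, n: int):
        self.b21 = np.ascontiguousarray(b21)
        self.n1, self.n = n1, n

    def add_to(self, V, coef):
        V[self.n1:, :self.n1] += coef * self.b21

    def matmat(self, B):
        out = np.zeros((self.n,) + B.shape[1:])
        out[:self.n1] = self.b21.T @ B[self.n1:]
        out[self.n1:] = self.b21 @ B[:self.n1]
        return out

    def trace_against(self, vi_lower):
        return float(2.0 * np.einsum("ij,ij->", vi_lower[self.n1:, :self.n1],
                                     self.b21))


def bivar_reml(y1, y2, grm: Grm, covariates=None, *, tol=1e-6,
               max_iter=100) -> BivarFit:
    """Fit the bivariate model on a combined-cohort GRM.

    ``y1`` and ``y2`` are length-n vectors over the combined samples with
    NaN marking individuals not on that side; the two sides must be
    disjoint and together cover all samples.  ``covariates`` (n x p, e.g.
    top-20 PCs computed on the combined cohort) are entered separately for
    each side, each with its own intercept.
    """
    y1 = np.asarray(y1, dtype=np.float64)
    y2 = np.asarray(y2, dtype=np.float64)
    n = y1.size
    if y2.size != n or grm.values.shape != (n, n):
        raise ParameterError("y1, y2 and the GRM must share one sample set")
    side1 = np.isfinite(y1)
    side2 = np.isfinite(y2)
    if (side1 & side2).any():
        raise ParameterError("cohorts must be disjoint (an individual has both phenotypes)")
    if not (side1 | side2).all():
        raise ParameterError("every sample must belong to one side")
    # sort samples so cohort 1 occupies a contiguous leading block: the
    # variance structure then lives in matrix blocks, which keeps every
    # REML iteration to one pass over the lower triangle
    order = np.argsort(side2, kind="stable")
    idx1 = order[: int(side1.sum())]
    idx2 = order[int(side1.sum()):]
    perm = np.concatenate([idx1, idx2])
    n1, n2 = idx1.size, idx2.size
    y = np.where(side1, y1, y2)[perm]
    A = grm.values[np.ix_(perm, perm)]
    d1 = np.zeros(n)
    d1[:n1] = 1.0
    d2 = 1.0 - d1

    if covariates is None:
        X = np.column_stack([d1, d2])
    else:
        covariates = np.asarray(covariates, dtype=np.float64)[perm]
        X = np.column_stack([d1, d2,
                             covariates * d1[:, None],
                             covariates * d2[:, None]])

    v1 = float(np.var(y[:n1]))
    v2 = float(np.var(y[n1:]))
    b21 = A[n1:, :n1]
    y1c = y[:n1] - y[:n1].mean()
    y2c = y[n1:] - y[n1:].mean()
    he_denom = float(np.sum(b21 * b21))
    he12 = float(y2c @ b21 @ y1c / he_denom) if he_denom > 0 else 0.0

    def project(theta):
        th = theta.copy()
        cap = 0.999 * np.sqrt(max(th[0], 0.0) * max(th[1], 0.0))
        th[2] = float(np.clip(th[2], -cap, cap))
        return th

    components = [_DiagBlock(A[:n1, :n1], 0, n1, n),
                  _DiagBlock(A[n1:, n1:], n1, n, n),
                  _CrossBlock(b21, n1, n),
                  DiagonalComponent(d1), DiagonalComponent(d2)]
    names = ["V(g1)", "V(g2)", "C(g12)", "V(e1)", "V(e2)"]
    init = np.array([v1 / 2, v2 / 2, project(np.array([v1 / 2, v2 / 2, he12]))[2],
                     v1 / 2, v2 / 2])
    fit = fit_variance_components(y, X, components, names, init=init,
                                  signed=(2,), tol=tol, max_iter=max_iter,
                                  project=project)
    sg1, sg2, sg12, se1, se2 = fit.theta

    # null: covariance fixed at zero -> the model decouples into two
    # independent univariate fits (same covariates per side)
    sub_fits = []
    for rows, orig in ((slice(0, n1), idx1), (slice(n1, n), idx2)):
        sub_grm = Grm(values=A[rows, rows],
                      n_snps_used=grm.n_snps_used[np.ix_(orig, orig)],
                      region=grm.region, sample_ids=grm.sample_ids[orig])
        cov_sub = covariates[rows] if covariates is not None else None
        sub_fits.append(reml_fit(y[rows], sub_grm, cov_sub, tol=tol,
                                 max_iter=max_iter))
    logl0 = sub_fits[0].loglik + sub_fits[1].loglik
    lrt = 2.0 * (fit.loglik - logl0)
    lrt_p = float(chi2.sf(max(lrt, 0.0), 1))

    floor_like = 1e-5 * max(v1, v2)
    reason = None
    if sg1 <= floor_like or sg2 <= floor_like:
        reason = ("genetic variance at the zero boundary for "
                  + ("side 1" if sg1 <= floor_like else "side 2"))
        rg, rg_se = float("nan"), float("nan")
    else:
        rg = sg12 / np.sqrt(sg1 * sg2)
        grad = np.array([-rg / (2 * sg1), -rg / (2 * sg2), 1.0 / np.sqrt(sg1 * sg2)])
        sub = fit.cov[np.ix_([0, 1, 2], [0, 1, 2])]
        rg_se = float(np.sqrt(max(grad @ sub @ grad, 0.0)))
        rg = float(np.clip(rg, -1.0, 1.0))
    se = dict(zip(names, fit.se))
    return BivarFit(sigma_g1=float(sg1), sigma_g2=float(sg2), sigma_g12=float(sg12),
                    sigma_e1=float(se1), sigma_e2=float(se2), se=se, rg=rg,
                    rg_se=rg_se, loglik=fit.loglik, loglik_null=logl0,
                    lrt_p=lrt_p, n_iter=fit.n_iter, converged=fit.converged,
                    rg_missing_reason=reason)


def bonferroni_adjust(p_nominal: float, n_tests: int) -> float:
    """min(1, n_tests * p)."""
    if not 0.0 < p_nominal <= 1.0:
        raise ParameterError("p must be in (0, 1]")
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return float(min(1.0, n_tests * p_nominal))
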