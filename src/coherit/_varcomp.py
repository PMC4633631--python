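"""Average-information REML for linear variance-component models.

Fits V(theta) = sum_i theta_i * M_i for symmetric component matrices M_i
(dense relationship matrices or diagonal residual masks) by maximizing the
restricted log-likelihood

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Updates use the average-information matrix

    AI_ij = 1/2 (M_i P y)' P (M_j P y)

with step-halving when a proposal leaves the feasible region or lowers the
likelihood, and an expectation-maximization fallback when Newton steps
fail outright.  Variance components are floored at a small positive
multiple of Var(y); signed components (genetic covariances) are kept
inside the positive-definite cone via a caller-supplied projection.

Implementation notes: each iteration performs exactly one Cholesky
factorization (of the proposed V) plus one in-place inverse (dpotri) of
the accepted factor; traces tr(V^-1 M) are taken against precomputed
strict-lower-triangle copies of each M so the inverse never needs to be
symmetrized, and all products with V^-1 go through triangular solves.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, lapack

from .errors import ComputationError


class DenseComponent:
    """A dense symmetric covariance design matrix."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.ascontiguousarray(matrix, dtype=np.float64)
        self._low = None
        self._diag = None

    def _split(self):
        if self._low is None:
            self._low = np.tril(self.matrix, -1)
            self._diag = np.ascontiguousarray(np.diagonal(self.matrix))
        return self._low, self._diag

    def add_to(self, V: np.ndarray, coef: float) -> None:
        V += coef * self.matrix

    def matmat(self, B: np.ndarray) -> np.ndarray:
        return self.matrix @ B

    def trace_against(self, vi_lower: np.ndarray) -> float:
        """tr(Vi M) given only the lower triangle of Vi (upper is junk)."""
        low, diag = self._split()
        return float(2.0 * np.einsum("ij,ij->", vi_lower, low)
                     + np.dot(np.diagonal(vi_lower), diag))


class DiagonalComponent:
    """A diagonal covariance design matrix (residual variance masks)."""

    def __init__(self, diag: np.ndarray):
        self.diag = np.asarray(diag, dtype=np.float64)

    def add_to(self, V: np.ndarray, coef: float) -> None:
        V[np.diag_indices_from(V)] += coef * self.diag

    def matmat(self, B: np.ndarray) -> np.ndarray:
        return self.diag[:, None] * B if B.ndim == 2 else self.diag * B

    def trace_against(self, vi_lower: np.ndarray) -> float:
        return float(np.dot(np.diagonal(vi_lower), self.diag))


@dataclass
class VarCompFit:
    theta: np.ndarray
    se: np.ndarray
    cov: np.ndarray  # sampling covariance of theta from the AI matrix
    loglik: float
    n_iter: int
    converged: bool
    names: list = field(default_factory=list)


@dataclass
class _State:
    """Everything derivable from one factorization of V(theta)."""

    theta: np.ndarray
    loglik: float
    factor: np.ndarray  # lower Cholesky factor of V (consumed by dpotri)
    Viy: np.ndarray
    Q: np.ndarray  # V^-1 X
    C: np.ndarray  # (X' V^-1 X)^-1
    Py: np.ndarray


def _build_V(components, theta, n) -> np.ndarray:
    V = np.zeros((n, n))
    for comp, t in zip(components, theta):
        comp.add_to(V, t)
    return V


def _evaluate(y, X, components, theta) -> _State | None:
    """One factorization: restricted logL plus the solves reused later."""
    n = y.size
    V = _build_V(components, theta, n)
    c, info = lapack.dpotrf(V, lower=1, overwrite_a=1)
    if info != 0:
        return None
    logdet = 2.0 * np.sum(np.log(np.diagonal(c)))
    sol = cho_solve((c, True), np.column_stack([y, X]))
    Viy, Q = sol[:, 0], sol[:, 1:]
    XtViX = X.T @ Q
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    C = np.linalg.inv(XtViX)
    XtViy = X.T @ Viy
    Py = Viy - Q @ (C @ XtViy)
    yPy = float(y @ Py)
    logl = -0.5 * (logdet + logdet_x + yPy)
    return _State(theta=theta, loglik=logl, factor=c, Viy=Viy, Q=Q, C=C, Py=Py)


def _derivatives(y, X, components, state: _State):
    """Score vector, AI matrix and tr(P M_i); consumes the state's factor."""
    k = len(components)
    n = y.size
    Q, C, Py = state.Q, state.C, state.Py
    U = np.empty((n, k))
    for i, comp in enumerate(components):
        U[:, i] = comp.matmat(Py)
    ViU = cho_solve((state.factor, True), U)
    PU = ViU - Q @ (C @ (Q.T @ U))
    AI = 0.5 * (U.T @ PU)
    AI = 0.5 * (AI + AI.T)
    # in-place inverse of V from the factor (factor is destroyed)
    vi, info = lapack.dpotri(state.factor, lower=1, overwrite_c=1)
    if info != 0:
        raise ComputationError("failed to invert V from its Cholesky factor")
    trPM = np.empty(k)
    score = np.empty(k)
    for i, comp in enumerate(components):
        MQ = comp.matmat(Q)
        tr_vi = comp.trace_against(vi)
        trPM[i] = tr_vi - float(np.trace(C @ (Q.T @ MQ)))
        score[i] = -0.5 * (trPM[i] - float(Py @ U[:, i]))
    return score, AI, trPM, U


def fit_variance_components(y, X, components, names=None, *, init=None,
                            signed=(), floor_frac=1e-6, tol=1e-6,
                            max_iter=100, project=None) -> VarCompFit:
    """Maximize the restricted likelihood over component coefficients.

    Parameters
    ----------
    y, X : response and fixed-effect design (X must include the intercept).
    components : list of DenseComponent / DiagonalComponent.
    signed : indices of coefficients allowed to be negative (covariances);
        all others are variances floored at ``floor_frac * Var(y)``.
    project : optional callable theta -> theta enforcing extra constraints
        after each proposal (e.g. |cov| <= sqrt(v1 v2)).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = y.size
    k = len(components)
    names = list(names) if names else [f"theta{i}" for i in range(k)]
    signed = set(signed)
    vary = float(np.var(y))
    if vary <= 0:
        raise ComputationError("response has zero variance")
    floor = floor_frac * vary

    def clamp(th):
        th = th.copy()
        for i in range(k):
            if i not in signed:
                th[i] = max(th[i], floor)
        if project is not None:
            th = project(th)
        return th

    if init is None:
        n_var = k - len(signed)
        init = np.array([0.0 if i in signed else vary / n_var for i in range(k)])
    theta = clamp(np.asarray(init, dtype=np.float64))

    state = _evaluate(y, X, components, theta)
    if state is None:
        raise ComputationError("initial variance components give a non-PD V")
    AI = np.eye(k)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            score, AI, trPM, U = _derivatives(y, X, components, state)
        except ComputationError:
            break
        if np.max(np.abs(score)) < 1e-10 * n:
            converged = True
            break
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(k), score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diagonal(AI), 1e-8)

        cand_state = None
        step = 1.0
        for _ in range(12):
            cand = clamp(theta + step * delta)
            cand_state = _evaluate(y, X, components, cand)
            if cand_state is not None and cand_state.loglik >= state.loglik - 1e-10:
                break
            cand_state = None
            step *= 0.5
        if cand_state is None:
            # EM fallback for the variance components
            cand = theta.copy()
            for i in range(k):
                if i in signed:
                    continue
                cand[i] = theta[i] + theta[i] ** 2 * (
                    float(state.Py @ U[:, i]) - trPM[i]) / n
            cand = clamp(cand)
            cand_state = _evaluate(y, X, components, cand)
            if cand_state is None or cand_state.loglik < state.loglik - 1e-8:
                converged = np.max(np.abs(score)) < 1e-4 * n
                break
        d = cand_state.loglik - state.loglik
        theta, state = cand, cand_state
        if abs(d) < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    se = np.sqrt(np.maximum(np.diagonal(cov), 0.0))
    return VarCompFit(theta=theta, se=se, cov=cov, loglik=float(state.loglik),
                      n_iter=n_iter, converged=converged, names=names)


def reml_null_loglik(y, X) -> float:
    """Restricted logL of the no-genetics model V = sigma_e^2 I.

    Uses the same three-term expression as the full model so that
    likelihood-ratio statistics are directly comparable.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - rank)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - rank) * np.log(sigma2) + logdet_xx + (n - rank))
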