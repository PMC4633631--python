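"""Population-structure handling: LD pruning, PCA, ancestry outliers.

Pruning follows the windowed greedy scheme of ``--indep-pairwise 50 10
0.2``: within each 50-SNP window, while any pair of retained SNPs has
r^2 above the cap, the member with the lower MAF is dropped (ties go to the
later position); the window then slides by 10 SNPs.  PCA is an
eigendecomposition of the standardized-genotype covariance over the pruned
SNPs, and ancestry outliers are samples more than 6 SD from the mean on
any of the top 10 components.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh

from .datatypes import MISSING, GenotypeData
from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class PruneSpec:
    window_snps: int = 50
    step_snps: int = 10
    r2_max: float = 0.2
    target_snps: int | None = 100_000  # deterministic thinning target

    def __post_init__(self):
        if self.step_snps > self.window_snps:
            raise ParameterError("step must be <= window")


@dataclass
class PcaResult:
    scores: np.ndarray  # n x k, column-orthogonal
    eigenvalues: np.ndarray
    sample_ids: np.ndarray
    outlier_flags: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i + 1}" for i in range(self.k)])
        df.insert(0, "IID", self.sample_ids)
        df.insert(0, "FID", self.sample_ids)
        return df


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Composite-LD r^2 between dosage columns, missing dropped pairwise."""
    obs = block != MISSING
    x = np.where(obs, block, 0).astype(np.float64)
    o = obs.astype(np.float64)
    n = o.T @ o
    sx = x.T @ o
    sxx = (x * x).T @ o
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var * var.T)
    r2[~np.isfinite(r2)] = 0.0
    return r2


def ld_prune(geno: GenotypeData, spec: PruneSpec = PruneSpec()) -> np.ndarray:
    """Greedy windowed LD pruning; returns the retained SNP identifiers.

    SNPs must be ordered by chromosome and position.  If more than
    ``spec.target_snps`` survive, a deterministic every-kth thinning
    reduces the list to approximately that size.
    """
    chroms = geno.snp_map["chrom"].to_numpy()
    bps = geno.snp_map["bp"].to_numpy()
    order_ok = all(
        (np.diff(bps[chroms == c]) >= 0).all() for c in np.unique(chroms))
    if not order_ok:
        raise ParameterError("SNPs must be sorted by chromosome and position")
    maf = geno.maf()
    keep = np.ones(geno.n_snps, dtype=bool)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        for start in range(0, idx.size, spec.step_snps):
            window = idx[start:start + spec.window_snps]
            active = window[keep[window]]
            if active.size < 2:
                continue
            r2 = _pairwise_r2(geno.dosage[:, active])
            np.fill_diagonal(r2, 0.0)
            alive = np.ones(active.size, dtype=bool)
            while True:
                sub = r2[np.ix_(alive, alive)]
                if sub.size == 0 or sub.max() <= spec.r2_max:
                    break
                aidx = np.flatnonzero(alive)
                jj, kk = np.unravel_index(np.argmax(sub), sub.shape)
                j, k = aidx[jj], aidx[kk]
                # drop the lower-MAF member; tie -> later position
                mj, mk = maf[active[j]], maf[active[k]]
                drop = j if (mj < mk or (mj == mk and j > k)) else k
                alive[drop] = False
            keep[active[~alive]] = False
    retained = geno.snp_ids[keep]
    if spec.target_snps is not None and retained.size > spec.target_snps:
        stride = int(np.ceil(retained.size / spec.target_snps))
        retained = retained[::stride]
    return retained


def compute_pca(geno: GenotypeData, pruned_ids=None, k: int = 20) -> PcaResult:
    """Top-k PCA of the standardized-genotype covariance.

    Missing dosages are mean-imputed per SNP.  The sign convention makes
    the largest-magnitude entry of each score vector positive, so results
    are deterministic.
    """
    if pruned_ids is not None:
        pruned_ids = np.asarray(pruned_ids)
        if pruned_ids.size == 0:
            raise InsufficientDataError("empty pruned SNP set")
        geno = geno.subset(snps=geno.snp_indices(pruned_ids))
    n, m = geno.n_samples, geno.n_snps
    if k >= min(n, m + 1):
        raise ParameterError(f"k={k} exceeds the available rank (n={n}, m={m})")
    obs = geno.dosage != MISSING
    x = np.where(obs, geno.dosage, 0).astype(np.float64)
    with np.errstate(invalid="ignore"):
        f = x.sum(axis=0) / (2.0 * obs.sum(axis=0))
    poly = (f > 0) & (f < 1)
    sd = np.sqrt(np.maximum(2 * f * (1 - f), 1e-300))
    z = (np.where(obs, x, 2 * f[None, :]) - 2 * f[None, :]) / sd[None, :]
    z[:, ~poly] = 0.0
    cov = (z @ z.T) / max(m, 1)
    vals, vecs = eigsh(cov, k=k, which="LA", v0=np.ones(n) / np.sqrt(n))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    for j in range(k):  # deterministic sign
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PcaResult(scores=scores, eigenvalues=vals,
                     sample_ids=geno.sample_ids.copy())


def remove_pca_outliers(pca: PcaResult, sd_threshold: float = 6.0,
                        top_k: int = 10, n_iterations: int = 1) -> np.ndarray:
    """Samples beyond ``sd_threshold`` SD on any of the top ``top_k`` PCs.

    A single pass by default; with more iterations the mean/SD are
    recomputed among the remaining samples each round (EIGENSTRAT-style).
    Returns the flagged sample identifiers.
    """
    k = min(top_k, pca.k)
    scores = pca.scores[:, :k]
    active = np.ones(scores.shape[0], dtype=bool)
    for _ in range(max(1, n_iterations)):
        mu = scores[active].mean(axis=0)
        sd = scores[active].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        out = active & (np.abs(scores - mu) > sd_threshold * sd).any(axis=1)
        if not out.any():
            break
        active &= ~out
    pca.outlier_flags = ~active
    return pca.sample_ids[~active]
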