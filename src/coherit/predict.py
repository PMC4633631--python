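"""Cross-validated linear-SVM disease prediction from top GWAS SNPs.

For each of 10 stratified folds, a GWAS is run on the training samples
only, SNPs are selected at each of a sweep of p-value thresholds, and a
linear SVM with inverse-frequency class weights is trained on mean-imputed
standardized training dosages and scored on the held-out fold.  Selection,
imputation means and standardization are all fitted on the training folds
only, so no information leaks from the evaluation fold.  Performance is
the area under the ROC curve (probability a random case outranks a random
control, ties counted 1/2), summarized as the mean and maximum over all
non-missing (threshold, fold) cells.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .assoc import gwas_logistic
from .datatypes import MISSING, GenotypeData
from .errors import ParameterError

DEFAULT_THRESHOLDS = (1e-5, 1e-6, 1e-7, 1e-8, 1e-9)


@dataclass(frozen=True)
class PredictionConfig:
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_folds: int = 10
    svm_cost: float = 1.0
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("need at least 2 folds")
        t = tuple(self.thresholds)
        if any(t[i] <= t[i + 1] for i in range(len(t) - 1)) and len(t) > 1:
            raise ParameterError("thresholds must be strictly decreasing")


@dataclass
class PredictionResult:
    """Per-(threshold, fold) AUCs and their summaries."""

    table: pd.DataFrame  # threshold fold n_snps auc
    auc_mean: float
    auc_max: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{"auc_mean": self.auc_mean, "auc_max": self.auc_max}])


def auc(decision_values, labels) -> float:
    """Rank-statistic AUC: P(score_case > score_control), ties 1/2."""
    s = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ParameterError("AUC needs both classes present")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def liability_auc_bound(h2_liab: float, K: float) -> float:
    """Closed-form AUC ceiling of any genotype-based predictor.

    The best achievable score is the true genetic liability value g with
    Var(g) = h2_liab; case/control means and variances of g follow from
    truncated-normal moments of the liability at threshold t = Phi^-1(1-K),
    and the two conditional distributions are treated as normal.
    """
    if h2_liab <= 0:
        return 0.5
    t = norm.isf(K)
    z = norm.pdf(t)
    i1 = z / K
    i0 = -z / (1 - K)
    v1 = 1 + t * i1 - i1 ** 2
    v0 = 1 + t * i0 - i0 ** 2
    m1, m0 = h2_liab * i1, h2_liab * i0
    s1 = h2_liab * (1 - h2_liab) + h2_liab ** 2 * v1
    s0 = h2_liab * (1 - h2_liab) + h2_liab ** 2 * v0
    return float(norm.cdf((m1 - m0) / np.sqrt(s1 + s0)))


def _standardize_train(train_dosage: np.ndarray):
    """Training-fold imputation means and scales (leakage-safe)."""
    obs = train_dosage != MISSING
    x = np.where(obs, train_dosage, 0).astype(np.float64)
    cnt = obs.sum(axis=0)
    mean = np.where(cnt > 0, x.sum(axis=0) / np.maximum(cnt, 1), 0.0)
    xs = np.where(obs, x, mean[None, :])
    sd = xs.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _features(dosage: np.ndarray, mean, sd) -> np.ndarray:
    obs = dosage != MISSING
    x = np.where(obs, dosage, 0).astype(np.float64)
    x = np.where(obs, x, mean[None, :])
    return (x - mean[None, :]) / sd[None, :]


def cv_svm_predict(geno: GenotypeData, case_status, covariates=None,
                   config: PredictionConfig = PredictionConfig(),
                   assoc_fn=None) -> PredictionResult:
    """Ten-fold cross-validated SVM prediction with per-fold SNP selection.

    ``assoc_fn(geno_train, y_train, train_indices)`` must return per-SNP
    p-values aligned with ``geno``'s SNPs; the default runs the additive
    logistic GWAS with the given covariates on the training samples only.  A threshold that
    selects zero SNPs in a fold yields a missing cell, not a failure.
    """
    y = np.asarray(case_status).astype(int)
    if assoc_fn is None:
        cov = None if covariates is None else np.asarray(covariates, dtype=float)

        def assoc_fn(sub, ysub, rows):
            c = cov[rows] if cov is not None else None
            return gwas_logistic(sub, ysub, c).table["P"].to_numpy()

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    rows_out = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        sub = geno.subset(samples=tr)
        pvals = np.asarray(assoc_fn(sub, y[tr], tr), dtype=float)
        for thr in config.thresholds:
            sel = np.flatnonzero(pvals < thr)
            if sel.size == 0:
                rows_out.append({"threshold": thr, "fold": fold,
                                 "n_snps": 0, "auc": np.nan})
                continue
            dtr = geno.dosage[np.ix_(tr, sel)]
            dte = geno.dosage[np.ix_(te, sel)]
            mean, sd = _standardize_train(dtr)
            Xtr = _features(dtr, mean, sd)
            Xte = _features(dte, mean, sd)
            clf = LinearSVC(C=config.svm_cost,
                            class_weight="balanced" if config.class_weighted else None,
                            dual="auto", max_iter=20_000)
            clf.fit(Xtr, y[tr])
            scores = clf.decision_function(Xte)
            rows_out.append({"threshold": thr, "fold": fold,
                             "n_snps": int(sel.size),
                             "auc": auc(scores, y[te])})
    table = pd.DataFrame(rows_out)
    vals = table["auc"].dropna()
    if vals.empty:
        warnings.warn("no threshold selected any SNPs in any fold; "
                      "all AUC cells missing", stacklevel=2)
        return PredictionResult(table=table, auc_mean=float("nan"),
                                auc_max=float("nan"))
    return PredictionResult(table=table, auc_mean=float(vals.mean()),
                            auc_max=float(vals.max()))
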