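"""Pathway mutation burden from MAF variant tables.

Computes per-sample pathway alteration flags ("at least one nonsynonymous
variant in a pathway gene"), tumor mutation burden (nonsynonymous count,
optionally per megabase of capture), an age-vs-alteration logistic
regression adjusted for cancer type, and the association between pathway
scores and TMB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ols_slope_rows
from .dysregulation import benchmark_association

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "read_maf",
    "pathway_alteration_matrix",
    "alteration_frequency",
    "compute_tmb",
    "LogisticFit",
    "logistic_fit",
    "score_tmb_association",
]

# conventional MAF nonsynonymous vocabulary (the maftools default)
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Splice_Site",
    "Translation_Start_Site",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
})

REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

DEFAULT_CAPTURE_MB = 38.0


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated MAF; '#'-prefixed lines are comments."""
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in REQUIRED_MAF_COLUMNS:
        if col not in maf.columns:
            raise ValueError(f"MAF is missing required column {col!r}")
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if maf[col].isna().any() or (maf[col].str.len() == 0).any():
            raise ValueError(f"MAF column {col!r} contains empty values")
    return maf


def _nonsynonymous(maf: pd.DataFrame) -> pd.DataFrame:
    return maf[maf["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]


def pathway_alteration_matrix(maf: pd.DataFrame, collection: dict[str, set[str]],
                              samples, include_silent: bool = False) -> pd.DataFrame:
    """Binary pathways x samples matrix: 1 iff >= 1 (nonsynonymous) pathway-gene variant.

    Samples absent from the MAF get 0 everywhere.  Duplicate identical MAF
    rows do not change the flags (>= 1 semantics).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("samples must be non-empty")
    use = maf if include_silent else _nonsynonymous(maf)
    hits = use.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"].agg(set)
    out = pd.DataFrame(0, index=list(collection), columns=samples, dtype=int)
    for sample in samples:
        genes = hits.get(sample)
        if not genes:
            continue
        for pathway, members in collection.items():
            if genes & members:
                out.loc[pathway, sample] = 1
    return out


def alteration_frequency(alteration: pd.DataFrame, cancer_labels=None) -> pd.DataFrame:
    """Fraction of altered samples per pathway, overall or per cancer type."""
    if cancer_labels is None:
        return alteration.mean(axis=1).to_frame("frequency")
    labels = pd.Series(np.asarray(cancer_labels), index=alteration.columns)
    return alteration.T.groupby(labels).mean().T


def compute_tmb(maf: pd.DataFrame, samples=None, per_mb: bool = False,
                capture_mb: float = DEFAULT_CAPTURE_MB) -> pd.Series:
    """Tumor mutation burden: nonsynonymous variant count per sample.

    With ``per_mb`` the count is divided by the capture size in megabases.
    Unlike alteration flags, TMB counts duplicates (count semantics).
    """
    if per_mb and capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    counts = _nonsynonymous(maf).groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    counts = counts.astype(float)
    if per_mb:
        counts = counts / capture_mb
    counts.name = "tmb"
    return counts


@dataclass
class LogisticFit:
    """IRLS logistic-regression fit with Wald inference."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    converged: bool
    iterations: int
    gradient_norm: float
    loglik_path: list[float] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log-likelihood of a Bernoulli GLM, numerically stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(altered_flags, ages, cancer_labels=None, tol: float = 1e-8,
                 max_iter: int = 25) -> LogisticFit:
    """Logistic regression of alteration status on age, adjusted for cancer type.

    Fitted by iteratively reweighted least squares (Newton with step-halving,
    so the log-likelihood is non-decreasing across iterations) to gradient
    tolerance ``tol``.  Cancer types are one-hot encoded with the first
    (lexicographic) level as reference.  Perfect separation is reported as a
    non-converged fit with a warning; estimates are returned as-is.
    """
    y = np.asarray(altered_flags, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("altered_flags must be binary")
    if np.unique(y).size < 2:
        raise ValueError("only one outcome class present")
    ages = np.asarray(ages, dtype=float)
    cols = [np.ones_like(ages), ages]
    names = ["intercept", "age"]
    if cancer_labels is not None:
        labels = pd.Series(np.asarray(cancer_labels))
        levels = sorted(labels.unique())
        for level in levels[1:]:
            cols.append((labels == level).to_numpy(dtype=float))
            names.append(f"cancer[{level}]")
    x = np.column_stack(cols)
    n, k = x.shape
    if n <= k:
        raise ValueError("more parameters than observations")

    beta = np.zeros(k)
    eta = x @ beta
    ll_path = [_loglik(y, eta)]
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm <= tol:
            converged = True
            it -= 1
            break
        w = mu * (1.0 - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll = _loglik(y, x @ candidate)
            if ll >= ll_path[-1] - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        eta = x @ beta
        ll_path.append(_loglik(y, eta))
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad_norm = float(np.max(np.abs(x.T @ (y - mu))))
        converged = grad_norm <= tol

    mu_fit = 1.0 / (1.0 + np.exp(-eta))
    # perfect separation: fitted probabilities reproduce the outcomes exactly,
    # the MLE diverges and the gradient vanishes along the way
    if np.max(np.abs(y - mu_fit)) < 1e-6:
        converged = False
    if not converged:
        warnings.warn(
            "logistic regression did not converge (possible perfect separation); "
            "estimates returned as-is", RuntimeWarning)

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return LogisticFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx),
        pvalues=pd.Series(p, index=idx),
        converged=converged,
        iterations=it,
        gradient_norm=grad_norm,
        loglik_path=ll_path,
    )


def score_tmb_association(scores, tmb, method: str = "spearman"):
    """Association between a pathway-score vector and per-sample TMB.

    Spearman rho and p by default; ``method="ols"`` returns the linear
    regression slope of score on TMB with its t-test p-value instead.
    """
    scores = np.asarray(scores, dtype=float)
    tmb = np.asarray(tmb, dtype=float)
    if method == "spearman":
        rho, p, _ = benchmark_association(scores, tmb, bins=min(10, scores.size))
        return rho, p
    if method == "ols":
        slope, _, p = ols_slope_rows(scores[None, :], tmb)
        return float(slope[0]), float(p[0])
    raise ValueError(f"unknown method {method!r}")
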