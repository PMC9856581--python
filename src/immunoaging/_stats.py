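"""Vectorized statistical primitives shared by the pathway- and gene-level analyses."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pooled_ttest_rows", "ols_slope_rows", "bh_adjust", "equal_frequency_mi"]


def pooled_ttest_rows(values: np.ndarray, group_flags: np.ndarray):
    """Two-sample pooled-variance t-test per row of ``values``.

    Parameters
    ----------
    values : (m, n) array, one test per row.
    group_flags : (n,) boolean array; effect = mean(flagged) - mean(unflagged).

    Returns
    -------
    effect, t, p : (m,) arrays.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(group_flags, dtype=bool)
    n1, n0 = int(flags.sum()), int((~flags).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per group for a pooled t-test")
    a, b = values[:, flags], values[:, ~flags]
    effect = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n0 - 1)
    df = n1 + n0 - 2
    se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # equal values in both groups: no evidence against the null
    p = np.where((se == 0) & (effect == 0), 1.0, p)
    return effect, t, p


def ols_slope_rows(values: np.ndarray, x: np.ndarray):
    """Simple linear regression of each row of ``values`` on the covariate ``x``.

    Returns slope, t and two-sided p arrays (df = n - 2).
    """
    values = np.asarray(values, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct covariate values")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = values - values.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    resid = yc - slope[:, None] * xc[None, :]
    df = n - 2
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
    # an exact fit has se == 0; a nonzero slope is then infinitely significant
    exact = (se == 0) & (slope != 0)
    if exact.any():
        t[exact] = np.sign(slope[exact]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((se == 0) & (slope == 0), 1.0, p)
    return slope, t, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def equal_frequency_mi(x, y, bins: int = 10) -> float:
    """Plug-in mutual information (bits) after equal-frequency discretization.

    Both variables are binned into ``bins`` classes of (near-)equal occupancy
    using a stable argsort, then MI is the plug-in estimate on the joint
    histogram.  Deterministic; ties are split by input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = x.size
    if n < bins:
        raise ValueError("need at least as many observations as bins")

    def _bin(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        b = np.empty(n, dtype=np.intp)
        b[order] = np.arange(n) * bins // n
        return b

    bx, by = _bin(x), _bin(y)
    joint = np.zeros((bins, bins), dtype=float)
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px @ py))
    return float(terms[mask].sum())
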