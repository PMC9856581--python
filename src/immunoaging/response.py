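"""Discrimination of immunotherapy responders by pathway scores.

Pathway scores are computed for a response-labelled cohort with ssGSEA and
each pathway's ability to separate responders (label 1) from non-responders
is quantified by the rank-based AUC (normalized Mann-Whitney U, ties count
one half) and a two-sided Wilcoxon rank-sum test.  Pathways with AUC
strictly above 0.7 are flagged as discriminative.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from ._stats import bh_adjust
from .scoring import DEFAULT_ALPHA, score_all

__all__ = [
    "roc_auc",
    "rank_sum_test",
    "pairwise_rank_sum",
    "evaluate_cohort",
    "AUC_FLAG_THRESHOLD",
]

AUC_FLAG_THRESHOLD = 0.7


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic.

    Equals the fraction of (responder, non-responder) pairs where the
    responder scores higher, counting ties one half.  Invariant under any
    strictly increasing transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size != y.size:
        raise ValueError("scores and labels must align")
    pos = y == 1
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s, method="average")
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p over all C(n1+n2, n1) group assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    n1, n = x.size, pooled.size
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        hits += abs(u - mu) >= dev - 1e-12
        total += 1
    return hits / total


def rank_sum_test(responder_scores, nonresponder_scores,
                  exact: bool = False) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of responder vs non-responder scores.

    Default: normal approximation with tie and continuity corrections.
    ``exact=True`` enumerates all group assignments (meant for
    n1 + n2 <= 10, where the normal approximation is coarsest).
    """
    x = np.asarray(responder_scores, dtype=float)
    y = np.asarray(nonresponder_scores, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 samples per group")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").statistic)
    if exact:
        return u, _exact_rank_sum_p(x, y)
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True).pvalue)
    return u, p


def pairwise_rank_sum(scores, categories) -> pd.DataFrame:
    """All pairwise rank-sum tests for a multi-category response, BH-adjusted."""
    s = np.asarray(scores, dtype=float)
    cats = pd.Series(np.asarray(categories))
    levels = sorted(cats.unique())
    if len(levels) < 2:
        raise ValueError("need at least two response categories")
    rows = []
    for a, b in combinations(levels, 2):
        u, p = rank_sum_test(s[cats == a], s[cats == b])
        rows.append({"group_a": a, "group_b": b, "U": u, "p_value": p})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def evaluate_cohort(cohort, collection: dict[str, set[str]] | None = None,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Score a response cohort and test each pathway's discrimination.

    ``cohort`` needs ``expression`` (genes x samples) and binary ``labels``
    aligned to samples (1 = responder).  Returns one row per pathway with
    AUC, U, p, BH-adjusted p, and a flag for AUC strictly above 0.7.
    """
    collection = collection if collection is not None else cohort.gene_sets
    labels = pd.Series(cohort.labels).reindex(cohort.expression.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    scores = score_all(cohort.expression, collection, alpha=alpha).scores
    rows = []
    for pathway, values in scores.iterrows():
        v = values.to_numpy(dtype=float)
        auc = roc_auc(v, y)
        u, p = rank_sum_test(v[y == 1], v[y == 0])
        rows.append({"pathway": pathway, "auc": auc, "U": u, "p_value": p})
    out = pd.DataFrame(rows).set_index("pathway")
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["flagged"] = out["auc"] > AUC_FLAG_THRESHOLD
    return out
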