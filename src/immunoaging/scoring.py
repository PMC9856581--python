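"""Single-sample gene-set enrichment (ssGSEA) scoring of immune-related pathways.

Each sample is scored independently from its within-sample expression ranking:
genes are ordered by decreasing expression, tied values receive average rank
values, and the enrichment score is the running difference between the
weighted in-set empirical CDF (weights ``rank**alpha``) and the uniform
out-of-set CDF, summed over all gene positions.  Raw pathway scores are then
scaled per pathway across the cohort to [0, 1] by MinMax normalization,

    X_normalized = (X - X_min) / (X_max - X_min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "ssgsea_score", "score_all", "minmax_normalize"]

DEFAULT_ALPHA = 0.25


@dataclass(frozen=True)
class ScoreMatrix:
    """Pathway x sample enrichment scores, raw or MinMax-normalized.

    ``xmin``/``xmax`` record the per-pathway extrema used by the
    normalization so downstream consumers can map scores back.
    """

    scores: pd.DataFrame
    normalized: bool = False
    xmin: pd.Series | None = None
    xmax: pd.Series | None = None

    @property
    def pathways(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


def _ranked_columns(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Per-column descending order (stable, gene-symbol tie-break) and rank values."""
    expr = expr.sort_index(kind="stable")  # symbol order makes ties order-independent
    x = expr.to_numpy(dtype=float)
    n = x.shape[0]
    constant = np.all(x == x[0, :], axis=0)
    if constant.any():
        bad = expr.columns[constant].tolist()
        raise ValueError(f"degenerate ranking: all-equal expression in samples {bad[:5]}")
    order = np.argsort(-x, axis=0, kind="stable")
    ranks = rankdata(x, axis=0, method="average")  # largest value -> rank n
    return order, ranks, expr.index


def _es_from_order(order: np.ndarray, ranks: np.ndarray, in_set: np.ndarray,
                   alpha: float) -> np.ndarray:
    """Enrichment scores for every sample given precomputed ordering and ranks."""
    n, m = order.shape
    n_in = int(in_set.sum())
    mask_ord = in_set[order]  # (n, m) membership along each sample's ordering
    ranks_ord = np.take_along_axis(ranks, order, axis=0)
    w = np.where(mask_ord, ranks_ord**alpha, 0.0)
    p_in = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
    p_out = np.cumsum(~mask_ord, axis=0) / float(n - n_in)
    return (p_in - p_out).sum(axis=0)


def ssgsea_score(expr: pd.DataFrame, geneset: set[str],
                 alpha: float = DEFAULT_ALPHA, name: str = "geneset") -> pd.Series:
    """Score one gene set in every sample of a genes x samples matrix.

    The score depends only on within-sample expression ranks, so any strictly
    increasing transform of a sample's expression leaves it unchanged.
    """
    present = sorted(geneset & set(expr.index))
    if len(present) < 2:
        raise ValueError(
            f"gene set {name!r}: needs >= 2 genes present in the matrix, "
            f"found {len(present)}"
        )
    if len(present) >= expr.shape[0]:
        raise ValueError(f"gene set {name!r} covers the whole gene universe")
    order, ranks, genes = _ranked_columns(expr)
    in_set = genes.isin(present)
    es = _es_from_order(order, ranks, in_set, alpha)
    return pd.Series(es, index=expr.columns, name=name)


def score_all(expr: pd.DataFrame, collection: dict[str, set[str]],
              alpha: float = DEFAULT_ALPHA) -> ScoreMatrix:
    """Score every pathway of a collection; returns a raw ScoreMatrix."""
    if not collection:
        raise ValueError("empty gene-set collection")
    order, ranks, genes = _ranked_columns(expr)
    universe = set(genes)
    rows = {}
    for pathway, members in collection.items():
        present = members & universe
        missing = members - universe
        if not present:
            raise ValueError(f"gene set {pathway!r} has no genes in the expression matrix")
        if missing:
            logger.warning("gene set %r: dropping %d genes absent from the matrix: %s",
                           pathway, len(missing), sorted(missing))
        if len(present) < 2:
            raise ValueError(f"gene set {pathway!r}: fewer than 2 genes present")
        in_set = genes.isin(present)
        rows[pathway] = _es_from_order(order, ranks, in_set, alpha)
    scores = pd.DataFrame(rows, index=expr.columns).T
    scores.index.name = "pathway"
    return ScoreMatrix(scores=scores, normalized=False)


def minmax_normalize(matrix: ScoreMatrix | pd.DataFrame) -> ScoreMatrix:
    """Scale each pathway's scores across samples to [0, 1]."""
    scores = matrix.scores if isinstance(matrix, ScoreMatrix) else matrix
    xmin = scores.min(axis=1)
    xmax = scores.max(axis=1)
    flat = xmax - xmin
    if (flat <= 0).any():
        bad = flat.index[flat <= 0].tolist()
        raise ValueError(f"zero score range for pathways {bad}")
    normalized = scores.sub(xmin, axis=0).div(flat, axis=0)
    return ScoreMatrix(scores=normalized, normalized=True, xmin=xmin, xmax=xmax)


def minmax_normalize_per_group(matrix: ScoreMatrix | pd.DataFrame,
                               groups: pd.Series) -> ScoreMatrix:
    """MinMax-normalize within each sample group (e.g. per cancer type).

    This is the default cohort definition for Eq.-style normalization when a
    pan-cancer matrix mixes cancer types; pass the full matrix to
    :func:`minmax_normalize` for a single global cohort instead.
    """
    scores = matrix.scores if isinstance(matrix, ScoreMatrix) else matrix
    groups = groups.reindex(scores.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    pieces = []
    for _, cols in scores.T.groupby(groups, sort=False):
        pieces.append(minmax_normalize(cols.T).scores)
    out = pd.concat(pieces, axis=1)[scores.columns]
    return ScoreMatrix(scores=out, normalized=True)
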