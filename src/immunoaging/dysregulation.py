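"""Tumor- and age-associated dysregulation of pathway scores.

Two differential analyses run per cancer type on the normalized pathway
scores: a two-group comparison of tumor vs normal samples (pooled-variance
t-test, BH-adjusted p < 0.05) and a linear age trend on tumor samples
(ordinary least squares, raw p < 0.05).  Their overlap and direction
concordance are then tested with Fisher's exact test over the pathway
universe, and pathway scores are benchmarked against aging gene-set scores
with Spearman correlation and a binned mutual-information estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, equal_frequency_mi, ols_slope_rows, pooled_ttest_rows
from .scoring import ScoreMatrix
from .simulate import age_group_midpoint

__all__ = [
    "tumor_differential",
    "age_trend",
    "bh_adjust",
    "anova_across_cancers",
    "classify_direction",
    "OverlapResult",
    "overlap_test",
    "benchmark_association",
    "model_ages",
]

TUMOR_ADJ_P = 0.05
AGE_RAW_P = 0.05


def _scores_frame(scores: ScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    return scores.scores if isinstance(scores, ScoreMatrix) else scores


def tumor_differential(scores: ScoreMatrix | pd.DataFrame, tumor_flags,
                       cancer: str = "all") -> pd.DataFrame:
    """Tumor-vs-normal differential score per pathway (pooled t, BH-adjusted).

    ``effect`` is mean(tumor) - mean(normal) in score units; a pathway is
    significant when its BH-adjusted p-value is below 0.05.
    """
    frame = _scores_frame(scores)
    flags = np.asarray(tumor_flags, dtype=bool)
    if flags.size != frame.shape[1]:
        raise ValueError("tumor_flags length must match the number of samples")
    if flags.all() or not flags.any():
        raise ValueError("both tumor and normal samples are required")
    effect, t, p = pooled_ttest_rows(frame.to_numpy(), flags)
    adj = bh_adjust(p)
    return pd.DataFrame({
        "pathway": frame.index,
        "cancer": cancer,
        "effect": effect,
        "t_statistic": t,
        "p_value": p,
        "adjusted_p": adj,
        "direction": np.sign(effect).astype(int),
        "significant": adj < TUMOR_ADJ_P,
    }).set_index("pathway")


def age_trend(scores: ScoreMatrix | pd.DataFrame, ages,
              cancer: str = "all") -> pd.DataFrame:
    """Per-pathway linear trend of score on age in years (OLS, raw p < 0.05)."""
    frame = _scores_frame(scores)
    ages = np.asarray(ages, dtype=float)
    if ages.size != frame.shape[1]:
        raise ValueError("ages length must match the number of samples")
    slope, t, p = ols_slope_rows(frame.to_numpy(), ages)
    return pd.DataFrame({
        "pathway": frame.index,
        "cancer": cancer,
        "effect": slope,
        "t_statistic": t,
        "p_value": p,
        "adjusted_p": bh_adjust(p),
        "direction": np.sign(slope).astype(int),
        "significant": p < AGE_RAW_P,
    }).set_index("pathway")


def model_ages(metadata: pd.DataFrame, include_normals: bool = False) -> pd.Series:
    """Ages used by the age model: exact years for tumors, bracket midpoints for normals.

    Normal samples emulate donors whose exact age is unknown and is
    represented by the decade-bracket midpoint.  With ``include_normals``
    False only tumor samples are returned.
    """
    meta = metadata if include_normals else metadata[metadata["is_tumor"]]
    ages = meta["age_years"].astype(float).copy()
    normals = ~meta["is_tumor"]
    if normals.any():
        ages.loc[normals] = [age_group_midpoint(b) for b in meta.loc[normals, "age_bracket"]]
    return ages


def anova_across_cancers(scores: ScoreMatrix | pd.DataFrame, cancer_labels) -> pd.DataFrame:
    """One-way ANOVA of each pathway's scores across cancer-type groups."""
    frame = _scores_frame(scores)
    labels = pd.Series(np.asarray(cancer_labels), index=frame.columns)
    groups = [frame.loc[:, labels == lab].to_numpy() for lab in labels.unique()]
    if len(groups) < 2 or any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    f, p = stats.f_oneway(*groups, axis=1)
    # all-identical groups: scipy returns nan; no between- or within-variance
    degenerate = ~np.isfinite(f)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"F": f, "p_value": p}, index=frame.index)


def classify_direction(tumor_record: Mapping, age_record: Mapping) -> str:
    """Joint tumor/age direction call for one pathway in one cancer.

    Returns "up/up", "up/down", "down/up", "down/down" when both analyses are
    significant, otherwise "not-both-significant".  Concordant means both
    significant with equal signs.
    """
    if not (tumor_record["significant"] and age_record["significant"]):
        return "not-both-significant"
    word = {1: "up", -1: "down"}
    return f"{word[int(tumor_record['direction'])]}/{word[int(age_record['direction'])]}"


@dataclass(frozen=True)
class OverlapResult:
    cancer: str
    a: int  # significant in both
    b: int  # tumor only
    c: int  # age only
    d: int  # neither
    odds_ratio: float
    p_value: float
    concordant_count: int
    discordant_count: int

    @property
    def log2_odds_ratio(self) -> float:
        """log2 OR capped at +/-10 for heatmap-style output."""
        if self.odds_ratio == 0:
            return -10.0
        if math.isinf(self.odds_ratio):
            return 10.0
        return float(np.clip(np.log2(self.odds_ratio), -10, 10))


def overlap_test(tumor_sig: Iterable[str], age_sig: Iterable[str],
                 universe: Iterable[str], mode: str = "any",
                 tumor_direction: Mapping[str, int] | None = None,
                 age_direction: Mapping[str, int] | None = None,
                 cancer: str = "all") -> OverlapResult:
    """Fisher's exact overlap of tumor- and age-dysregulated pathway sets.

    ``mode`` "any" tests raw set overlap.  "same-direction" (resp.
    "opposite") removes pathways whose tumor and age directions disagree
    (resp. agree) from the age set before building the 2x2 table, so the test
    asks whether concordant (resp. discordant) dysregulation is enriched.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty pathway universe")
    tumor_sig, age_sig = set(tumor_sig), set(age_sig)
    if not tumor_sig <= universe or not age_sig <= universe:
        raise ValueError("significant sets must be subsets of the universe")

    both = tumor_sig & age_sig
    concordant = discordant = 0
    if tumor_direction is not None and age_direction is not None:
        concordant = sum(1 for p in both if tumor_direction[p] == age_direction[p])
        discordant = len(both) - concordant
        if mode == "same-direction":
            age_sig = age_sig - {p for p in both if tumor_direction[p] != age_direction[p]}
        elif mode == "opposite":
            age_sig = age_sig - {p for p in both if tumor_direction[p] == age_direction[p]}
        elif mode != "any":
            raise ValueError(f"unknown mode {mode!r}")
    elif mode != "any":
        raise ValueError("direction maps are required for direction-aware modes")

    a = len(tumor_sig & age_sig)
    b = len(tumor_sig - age_sig)
    c = len(age_sig - tumor_sig)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else (0.0 if a * d == 0 else math.inf))
    return OverlapResult(cancer=cancer, a=a, b=b, c=c, d=d, odds_ratio=odds,
                         p_value=float(p), concordant_count=concordant,
                         discordant_count=discordant)


def benchmark_association(irp_scores, arg_scores, bins: int = 10):
    """Spearman rho/p and mutual information (bits) between two score vectors.

    Used to validate the aging character of pathway scores against benchmark
    aging gene-set scores; MI uses equal-frequency binning (plug-in estimate).
    """
    x = np.asarray(irp_scores, dtype=float)
    y = np.asarray(arg_scores, dtype=float)
    if x.size != y.size or x.size < 8:
        raise ValueError("need paired vectors of length >= 8")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    mi = equal_frequency_mi(x, y, bins=bins)
    return float(rho), float(p), mi
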