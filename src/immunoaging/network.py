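"""Network-based prioritization of immune/aging drug-target genes.

Stage 1, per cancer type: genes significantly dysregulated both between
tumor and normal and along age are ranked by the rank product

    R_IMG = R_FC1 x R_FC2,

where R_FC1 ranks genes by descending |log2 tumor fold change| and R_FC2 by
descending |log2 age (old-vs-young) fold change|.  The top 10% of the ranked
list seeds a random walk with restart (RWR) on the protein-protein
interaction network,

    P_{t+1} = gamma * P0 + (1 - gamma) * W * P_t,

with W the column-normalized adjacency, and the top 1% of propagated genes
is kept.  Stage 2: the genes shared across all cancer types re-seed a second
RWR whose ranking (reported as percentiles) is mapped to a drug-gene
interaction table to produce candidate targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import rankdata

from ._stats import bh_adjust, ols_slope_rows, pooled_ttest_rows

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "PropagationState",
    "gene_fold_changes",
    "rank_product",
    "select_seed_genes",
    "rwr",
    "rwr_exact",
    "top_fraction",
    "integrate_shared",
    "two_stage_prioritize",
    "map_drug_targets",
    "run_two_stage_pipeline",
]

DEFAULT_GAMMA = 0.7
DEFAULT_SEED_FRACTION = 0.10
DEFAULT_TOP_FRACTION = 0.01


@dataclass(frozen=True)
class PPINetwork:
    """Largest connected component of an undirected gene network.

    ``w`` is the column-stochastic transition matrix (W_ij = A_ij / deg(j));
    nodes excluded as outside the analyzed component are reported.
    """

    nodes: tuple[str, ...]
    w: sparse.csc_matrix
    graph: nx.Graph
    excluded: tuple[str, ...] = ()

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "PPINetwork":
        g = nx.Graph(g)  # drop parallel edges if any
        g.remove_edges_from(nx.selfloop_edges(g))
        components = sorted(nx.connected_components(g), key=len, reverse=True)
        if not components:
            raise ValueError("empty network")
        keep = components[0]
        excluded = tuple(sorted(set(g.nodes) - keep))
        if excluded:
            logger.warning("excluding %d nodes outside the largest connected component",
                           len(excluded))
        sub = g.subgraph(keep)
        nodes = tuple(sorted(sub.nodes))
        adj = nx.to_scipy_sparse_array(sub, nodelist=list(nodes), format="csc",
                                       dtype=float)
        deg = np.asarray(adj.sum(axis=0)).ravel()
        w = (adj @ sparse.diags(1.0 / deg)).tocsc()
        return cls(nodes=nodes, w=w, graph=sub, excluded=excluded)

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "PPINetwork":
        g = nx.from_pandas_edgelist(edges, source=edges.columns[0],
                                    target=edges.columns[1])
        return cls.from_graph(g)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.nodes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in the network component: {sorted(missing)[:5]}")
        return np.array([lookup[g] for g in genes], dtype=np.intp)


@dataclass
class PropagationState:
    """Result of one RWR run: final probabilities plus convergence evidence."""

    probabilities: pd.Series
    p0: pd.Series
    gamma: float
    iterations: int
    residual: float
    max_mass_error: float  # largest |sum(P_t) - 1| seen across iterations


def gene_fold_changes(expr: pd.DataFrame, tumor_flags, ages,
                      tumor_adj_p: float = 0.05,
                      age_raw_p: float = 0.05) -> pd.DataFrame:
    """Per-gene tumor (FC1) and age (FC2) fold changes on log2(TPM+1).

    FC1 = 2^(mean log2(TPM+1) tumor - normal).  FC2 = 2^(mean old - young)
    among tumor samples, old = age >= cohort median age.  The result is
    restricted to genes passing both significance filters (pooled t with
    BH-adjusted p < ``tumor_adj_p`` for tumor; OLS on age with raw
    p < ``age_raw_p``), mirroring the pathway-level dysregulation tests at
    gene level.
    """
    flags = np.asarray(tumor_flags, dtype=bool)
    if flags.size != expr.shape[1]:
        raise ValueError("tumor_flags length must match sample count")
    if not flags.any() or flags.all():
        raise ValueError("both tumor and normal samples are required")
    log2x = np.log2(expr.to_numpy(dtype=float) + 1.0)

    effect, _, p_tumor = pooled_ttest_rows(log2x, flags)
    adj_tumor = bh_adjust(p_tumor)
    fc1 = 2.0**effect

    tumor_ages = np.asarray(ages, dtype=float)
    if tumor_ages.size == flags.sum():
        pass
    elif tumor_ages.size == flags.size:
        tumor_ages = tumor_ages[flags]
    else:
        raise ValueError("ages must align with tumor samples or all samples")
    tumor_x = log2x[:, flags]
    slope_p = ols_slope_rows(tumor_x, tumor_ages)[2]
    median_age = np.median(tumor_ages)
    old = tumor_ages >= median_age
    if not old.any() or old.all():
        raise ValueError("old/young split is empty; ages are degenerate")
    fc2 = 2.0**(tumor_x[:, old].mean(axis=1) - tumor_x[:, ~old].mean(axis=1))

    keep = (adj_tumor < tumor_adj_p) & (slope_p < age_raw_p)
    return pd.DataFrame({"fc1": fc1, "fc2": fc2}, index=expr.index)[keep]


def rank_product(fc1_map, fc2_map) -> pd.DataFrame:
    """Rank-product prioritization: R_IMG = R_FC1 x R_FC2, small = strong.

    Ranks are over descending |log2 FC| (rank 1 = largest magnitude), tied
    values get average ranks; output is sorted by ascending R_IMG with ties
    broken by gene symbol.
    """
    fc1 = pd.Series(fc1_map, dtype=float)
    fc2 = pd.Series(fc2_map, dtype=float)
    if set(fc1.index) != set(fc2.index):
        diff = set(fc1.index) ^ set(fc2.index)
        raise ValueError(f"fold-change maps cover different genes: {sorted(diff)[:5]}")
    if len(fc1) < 2:
        raise ValueError("need at least 2 genes to rank")
    fc2 = fc2.reindex(fc1.index)
    r1 = rankdata(-np.abs(np.log2(fc1.to_numpy())), method="average")
    r2 = rankdata(-np.abs(np.log2(fc2.to_numpy())), method="average")
    out = pd.DataFrame({
        "gene": fc1.index,
        "fc1": fc1.to_numpy(),
        "fc2": fc2.to_numpy(),
        "r_fc1": r1,
        "r_fc2": r2,
        "r_img": r1 * r2,
    })
    return out.sort_values(["r_img", "gene"], kind="stable").reset_index(drop=True)


def select_seed_genes(priorities: pd.DataFrame, network: PPINetwork,
                      fraction: float = DEFAULT_SEED_FRACTION) -> list[str]:
    """Top ``ceil(fraction * n)`` genes by ascending R_IMG, kept to network nodes."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(priorities))
    top = priorities["gene"].head(n_top).tolist()
    in_network = set(network.nodes)
    seeds = [g for g in top if g in in_network]
    dropped = [g for g in top if g not in in_network]
    if dropped:
        logger.warning("dropping %d seed genes absent from the network: %s",
                       len(dropped), dropped[:5])
    if not seeds:
        raise ValueError("no seed genes present in the network")
    return seeds


def _restart_vector(network: PPINetwork, seeds) -> np.ndarray:
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    idx = network.index_of(seeds)
    p0 = np.zeros(network.n)
    p0[idx] = 1.0 / len(seeds)
    return p0


def rwr(network: PPINetwork, seeds, gamma: float = DEFAULT_GAMMA,
        tol: float = 1e-10, max_iter: int = 10000) -> PropagationState:
    """Iterate P_{t+1} = gamma*P0 + (1-gamma)*W*P_t to stationarity.

    P0 is uniform over the seed genes.  Convergence is by L1 change below
    ``tol``; probability mass is conserved at every iteration (tracked in
    ``max_mass_error``).
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    p0 = _restart_vector(network, seeds)
    p = p0.copy()
    max_mass_error = abs(p.sum() - 1.0)
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        p_next = gamma * p0 + (1.0 - gamma) * (network.w @ p)
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        max_mass_error = max(max_mass_error, abs(p.sum() - 1.0))
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {max_iter} iterations (L1 residual {residual:.3e})")
    series = pd.Series(p, index=list(network.nodes), name="probability")
    return PropagationState(probabilities=series,
                           p0=pd.Series(p0, index=list(network.nodes)),
                           gamma=gamma, iterations=iteration,
                           residual=residual, max_mass_error=float(max_mass_error))


def rwr_exact(network: PPINetwork, seeds, gamma: float = DEFAULT_GAMMA) -> pd.Series:
    """Closed-form stationary RWR: solve (I - (1-gamma)W) P = gamma*P0.

    Serves as the brute-force oracle for the iterative solver; the system is
    nonsingular for gamma > 0 with a column-stochastic W.
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    p0 = _restart_vector(network, seeds)
    system = sparse.identity(network.n, format="csc") - (1.0 - gamma) * network.w
    p = spsolve(system.tocsc(), gamma * p0)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("singular RWR system")
    return pd.Series(p, index=list(network.nodes), name="probability")


def top_fraction(probabilities: pd.Series, fraction: float = DEFAULT_TOP_FRACTION) -> list[str]:
    """Top ``ceil(fraction * n)`` genes by descending probability.

    Ties at the cutoff keep the lexicographically smaller gene symbol.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(probabilities))
    order = probabilities.to_frame("p").reset_index()
    order.columns = ["gene", "p"]
    order = order.sort_values(["p", "gene"], ascending=[False, True], kind="stable")
    return order["gene"].head(n_top).tolist()


def integrate_shared(per_condition_top_sets, min_conditions: int | None = None) -> set[str]:
    """Genes shared across per-cancer top sets (strict intersection by default).

    With ``min_conditions=k`` a gene needs membership in >= k of the n sets.
    """
    sets = [set(s) for s in per_condition_top_sets]
    if not sets:
        raise ValueError("need at least one gene set")
    if min_conditions is None:
        shared = set.intersection(*sets)
        if not shared:
            raise ValueError(
                "no genes shared across all conditions; relax with min_conditions")
        return shared
    if not 1 <= min_conditions <= len(sets):
        raise ValueError("min_conditions must be between 1 and the number of sets")
    counts: dict[str, int] = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_conditions}


def two_stage_prioritize(network: PPINetwork, shared_genes,
                         gamma: float = DEFAULT_GAMMA,
                         fraction: float = DEFAULT_TOP_FRACTION,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Second-stage RWR seeded by the shared genes.

    Returns the full ranked table (gene, probability, rank, percentile with
    percentile = rank / n over descending probability, ties by gene symbol)
    and the final candidate list, the top ``fraction`` of network genes.
    Seed genes remain eligible for the candidate set.
    """
    state = rwr(network, shared_genes, gamma=gamma)
    table = state.probabilities.to_frame("probability").reset_index()
    table.columns = ["gene", "probability"]
    table = table.sort_values(["probability", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["percentile"] = table["rank"] / len(table)
    table["is_seed"] = table["gene"].isin(set(shared_genes))
    candidates = table["gene"].head(math.ceil(fraction * len(table))).tolist()
    return table, candidates


def map_drug_targets(candidates: pd.DataFrame | list[str],
                     interaction_table: pd.DataFrame,
                     keep_unmatched: bool = False) -> pd.DataFrame:
    """Join candidate genes with a (gene, compound) interaction table.

    Candidate order is preserved; genes without compounds are dropped unless
    ``keep_unmatched`` retains them with an empty compound list.
    """
    if isinstance(candidates, pd.DataFrame):
        frame = candidates.copy()
        if "gene" not in frame.columns:
            raise ValueError("candidate table needs a 'gene' column")
    else:
        frame = pd.DataFrame({"gene": list(candidates)})
    if not {"gene", "compound"} <= set(interaction_table.columns):
        raise ValueError("interaction table must have 'gene' and 'compound' columns")
    compounds = (interaction_table.groupby("gene")["compound"]
                 .agg(lambda c: sorted(set(c))))
    frame["compounds"] = [compounds.get(g, []) for g in frame["gene"]]
    if not keep_unmatched:
        frame = frame[frame["compounds"].map(len) > 0]
    return frame.reset_index(drop=True)


def run_two_stage_pipeline(expression: pd.DataFrame, metadata: pd.DataFrame,
                           network: PPINetwork,
                           gamma: float = DEFAULT_GAMMA,
                           seed_fraction: float = DEFAULT_SEED_FRACTION,
                           top_frac: float = DEFAULT_TOP_FRACTION,
                           min_conditions: int | None = None,
                           ) -> dict:
    """Full per-cancer rank-product -> RWR -> intersection -> re-RWR pipeline.

    ``metadata`` must carry ``cancer``, ``is_tumor`` and ``age_years``
    columns indexed by sample.  Returns a dict with per-cancer seed lists and
    top sets, the shared gene set, the final ranked table and the candidate
    list.
    """
    per_cancer_seeds: dict[str, list[str]] = {}
    per_cancer_top: dict[str, list[str]] = {}
    for cancer, meta in metadata.groupby("cancer"):
        expr = expression[meta.index]
        flags = meta["is_tumor"].to_numpy(dtype=bool)
        ages = meta.loc[meta["is_tumor"], "age_years"].to_numpy(dtype=float)
        fc = gene_fold_changes(expr, flags, ages)
        priorities = rank_product(fc["fc1"], fc["fc2"])
        seeds = select_seed_genes(priorities, network, fraction=seed_fraction)
        state = rwr(network, seeds, gamma=gamma)
        per_cancer_seeds[cancer] = seeds
        per_cancer_top[cancer] = top_fraction(state.probabilities, fraction=top_frac)
    shared = integrate_shared(per_cancer_top.values(), min_conditions=min_conditions)
    table, candidates = two_stage_prioritize(network, shared, gamma=gamma,
                                             fraction=top_frac)
    return {
        "per_cancer_seeds": per_cancer_seeds,
        "per_cancer_top": per_cancer_top,
        "shared": shared,
        "table": table,
        "candidates": candidates,
    }
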