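"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the shape of a pan-cancer study:
log-normal TPM expression with planted tumor log-fold-changes and linear age
trends, decade age brackets with the midpoint convention used for donors
whose exact age is unknown, scale-free protein-interaction networks with a
densely wired driver module, toy MAF mutation tables, and responder /
non-responder expression cohorts.  Driver genes couple all three signals
(tumor effect, age effect, network module) so that end-to-end recovery by
the prioritization pipeline is well-posed, and every planted gene is
recorded in a ground-truth listing.

All randomness flows through one integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ResponseCohort",
    "age_group_midpoint",
    "generate_cohort",
    "generate_network",
    "generate_maf",
    "generate_response_cohort",
    "write_cohort",
]

_BRACKET_RE = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$")

NONSYNONYMOUS_DRAW = {
    "Missense_Mutation": 0.70,
    "Nonsense_Mutation": 0.10,
    "Frame_Shift_Del": 0.05,
    "Frame_Shift_Ins": 0.05,
    "Splice_Site": 0.05,
    "In_Frame_Del": 0.05,
}


def age_group_midpoint(bracket: str) -> float:
    """Representative age of a bracket label "lo-hi": (lo + hi + 1) / 2.

    For decade brackets this reproduces the convention of assigning 25 to
    every donor in the 20-29 group.  Accepts hyphen or en-dash separators.
    """
    m = _BRACKET_RE.match(str(bracket))
    if m is None:
        raise ValueError(f"malformed age bracket {bracket!r}; expected 'lo-hi'")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo > hi:
        raise ValueError(f"age bracket {bracket!r} has lo > hi")
    return (lo + hi + 1) / 2


def _bracket(age: int) -> str:
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pan-cancer cohort.

    Expression is simulated on the log2(TPM + 1) scale as
    ``baseline + tumor_effect + age_slope * (age - 50) + noise`` and
    back-transformed, so planted effects are exact log2 fold changes.
    """

    n_genes: int = 2000
    n_cancers: int = 3
    n_tumor: int = 80
    n_normal: int = 80
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    planted_tumor_lfc: float = 2.0
    planted_age_slope: float = 0.03
    noise_sd: float = 1.0
    cancer_shift_sd: float = 0.3
    n_driver_genes: int = 40
    n_tumor_dysregulated: int = 200
    n_age_dysregulated: int = 200
    network_nodes: int = 2000
    network_attach: int = 3
    n_pathways: int = 17
    pathway_size: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cancers", "n_tumor", "n_normal",
                     "n_driver_genes", "network_nodes", "network_attach",
                     "n_pathways", "pathway_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("baseline_log_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.network_attach >= self.network_nodes:
            raise ValueError("network_attach must be smaller than network_nodes")
        if self.n_driver_genes > min(self.n_tumor_dysregulated, self.n_age_dysregulated):
            raise ValueError("drivers must fit inside both planted gene lists")
        plantable = min(self.n_genes, self.network_nodes)
        needed = (self.n_tumor_dysregulated + self.n_age_dysregulated
                  - self.n_driver_genes)
        if needed > plantable:
            raise ValueError("not enough plantable genes for the requested effects")
        if self.n_pathways * self.pathway_size > self.n_genes:
            raise ValueError("pathways cannot cover more genes than exist")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame            # genes x samples, TPM
    metadata: pd.DataFrame              # sample_id -> cancer, is_tumor, age_years, age_bracket
    gene_sets: dict[str, set[str]]
    truth: dict[str, list[str]]         # tumor_dysregulated / age_dysregulated / drivers
    tumor_signs: pd.Series              # +1/-1 per tumor-planted gene
    age_signs: pd.Series
    config: SimulationConfig


@dataclass
class ResponseCohort:
    expression: pd.DataFrame
    labels: pd.Series                   # 1 = responder
    gene_sets: dict[str, set[str]]
    shifted_pathway: str


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate expression + metadata for ``n_cancers`` cancer types.

    Planted tumor-dysregulated genes receive a +/- ``planted_tumor_lfc``
    shift in tumor samples; age-dysregulated genes a +/-
    ``planted_age_slope`` log2-units-per-year trend centred at age 50.
    Drivers carry both effects and are a subset of both truth lists.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    plantable = min(config.n_genes, config.network_nodes)
    perm = rng.permutation(plantable)
    nd = config.n_driver_genes
    nt_extra = config.n_tumor_dysregulated - nd
    na_extra = config.n_age_dysregulated - nd
    drivers_idx = perm[:nd]
    tumor_idx = np.concatenate([drivers_idx, perm[nd:nd + nt_extra]])
    age_idx = np.concatenate([drivers_idx, perm[nd + nt_extra:nd + nt_extra + na_extra]])

    tumor_sign = rng.choice([-1.0, 1.0], size=tumor_idx.size)
    age_sign = rng.choice([-1.0, 1.0], size=age_idx.size)
    tumor_effect = np.zeros(config.n_genes)
    tumor_effect[tumor_idx] = tumor_sign * config.planted_tumor_lfc
    age_effect = np.zeros(config.n_genes)
    age_effect[age_idx] = age_sign * config.planted_age_slope

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          config.n_genes)

    blocks, meta_rows = [], []
    per_cancer = config.n_tumor + config.n_normal
    for c in range(config.n_cancers):
        cancer = f"C{c + 1:02d}"
        cancer_offset = rng.normal(0.0, config.cancer_shift_sd, config.n_genes)
        is_tumor = np.array([True] * config.n_tumor + [False] * config.n_normal)
        ages = rng.integers(20, 90, size=per_cancer)
        log2x = (baseline[:, None] + cancer_offset[:, None]
                 + np.outer(tumor_effect, is_tumor.astype(float))
                 + np.outer(age_effect, ages - 50.0)
                 + rng.normal(0.0, config.noise_sd, (config.n_genes, per_cancer)))
        blocks.append(np.clip(2.0**log2x - 1.0, 0.0, None))
        for j in range(per_cancer):
            kind = "T" if is_tumor[j] else "N"
            idx = j if is_tumor[j] else j - config.n_tumor
            meta_rows.append({
                "sample_id": f"{cancer}_{kind}{idx:03d}",
                "cancer": cancer,
                "is_tumor": bool(is_tumor[j]),
                "age_years": int(ages[j]),
                "age_bracket": _bracket(int(ages[j])),
            })

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    expression = pd.DataFrame(np.hstack(blocks), index=genes,
                              columns=metadata.index)

    gene_arr = np.array(genes)
    truth = {
        "tumor_dysregulated": sorted(gene_arr[tumor_idx]),
        "age_dysregulated": sorted(gene_arr[age_idx]),
        "drivers": sorted(gene_arr[drivers_idx]),
    }

    # pathways: planted genes first so early sets carry signal, then the rest
    planted_order = np.concatenate([
        drivers_idx, perm[nd:nd + nt_extra], perm[nd + nt_extra:nd + nt_extra + na_extra]])
    rest = np.setdiff1d(np.arange(config.n_genes), planted_order)
    ordering = np.concatenate([planted_order, rest])
    gene_sets = {
        f"IRP{k + 1:02d}": set(gene_arr[ordering[k * config.pathway_size:
                                                 (k + 1) * config.pathway_size]])
        for k in range(config.n_pathways)
    }

    return SyntheticCohort(
        expression=expression,
        metadata=metadata,
        gene_sets=gene_sets,
        truth=truth,
        tumor_signs=pd.Series(tumor_sign, index=gene_arr[tumor_idx]).sort_index(),
        age_signs=pd.Series(age_sign, index=gene_arr[age_idx]).sort_index(),
        config=config,
    )


def generate_network(n_nodes: int, attach: int, drivers=(), seed: int = 0) -> nx.Graph:
    """Scale-free (preferential-attachment) gene network with a driver clique.

    Nodes are labelled like the cohort's genes.  All pairwise edges among
    ``drivers`` are added so the driver module is densely connected; the
    graph has no self-loops or duplicate edges and is connected.
    """
    if attach >= n_nodes:
        raise ValueError("attach must be smaller than n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, attach, seed=int(seed))
    mapping = dict(enumerate(_gene_names(n_nodes)))
    g = nx.relabel_nodes(g, mapping)
    drivers = list(drivers)
    unknown = set(drivers) - set(g.nodes)
    if unknown:
        raise ValueError(f"driver genes not in the network: {sorted(unknown)[:5]}")
    for i, u in enumerate(drivers):
        for v in drivers[i + 1:]:
            g.add_edge(u, v)
    return g


def generate_maf(samples, genes, rate: float, seed: int = 0,
                 silent_fraction: float = 0.10) -> pd.DataFrame:
    """Toy MAF: Poisson(rate) nonsynonymous variants per sample, ~10% silent extra."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    genes = np.asarray(list(genes))
    classes = np.array(list(NONSYNONYMOUS_DRAW))
    probs = np.array(list(NONSYNONYMOUS_DRAW.values()))
    rows = []
    for sample in samples:
        k = rng.poisson(rate)
        for gene in rng.choice(genes, size=k):
            rows.append((gene, sample, rng.choice(classes, p=probs)))
        for gene in rng.choice(genes, size=rng.poisson(rate * silent_fraction)):
            rows.append((gene, sample, "Silent"))
    return pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                       "Variant_Classification"])


def generate_response_cohort(n_resp: int, n_nonresp: int, shift: float,
                             seed: int = 0, n_genes: int = 340,
                             n_pathways: int = 17,
                             pathway_size: int = 20) -> ResponseCohort:
    """Immunotherapy-style cohort: responders carry a pathway-wide log2 shift.

    Genes of the first pathway are shifted by ``shift`` log2 units in
    responder samples; all other genes are exchangeable between classes.
    """
    if n_resp < 1 or n_nonresp < 1:
        raise ValueError("both classes need at least one sample")
    if n_pathways * pathway_size > n_genes:
        raise ValueError("pathways cannot cover more genes than exist")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    gene_sets = {
        f"IRP{k + 1:02d}": set(genes[k * pathway_size:(k + 1) * pathway_size])
        for k in range(n_pathways)
    }
    target = "IRP01"
    n = n_resp + n_nonresp
    labels = np.array([1] * n_resp + [0] * n_nonresp)
    baseline = rng.normal(3.0, 1.5, n_genes)
    log2x = baseline[:, None] + rng.normal(0.0, 1.0, (n_genes, n))
    target_mask = np.array([g in gene_sets[target] for g in genes])
    log2x[np.ix_(target_mask, labels == 1)] += shift
    sample_ids = [f"R{i:03d}" if labels[i] else f"NR{i:03d}" for i in range(n)]
    expression = pd.DataFrame(np.clip(2.0**log2x - 1.0, 0.0, None),
                              index=genes, columns=sample_ids)
    return ResponseCohort(expression=expression,
                          labels=pd.Series(labels, index=sample_ids, name="response"),
                          gene_sets=gene_sets, shifted_pathway=target)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write expression, metadata, GMT and truth files for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_expression(cohort.expression, outdir / "expression.tsv")
    _io.write_metadata(cohort.metadata, outdir / "metadata.tsv")
    _io.write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    _io.write_truth(cohort.truth, outdir / "truth.json")
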