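"""Readers and writers for the plain-text formats used throughout the package.

Expression matrices, sample metadata, pathway scores and network edge lists
travel as TSV; gene sets as GMT; somatic variants as MAF.  Everything is
round-trippable and deterministic so that simulated fixtures hash equal
across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_drug_table",
    "read_scores",
    "write_scores",
    "write_truth",
    "read_truth",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (TSV, first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    values = df.to_numpy()
    import numpy as np

    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata: sample_id, cancer, is_tumor, age_years, age_bracket."""
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = {"cancer", "is_tumor", "age_years", "age_bracket"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    meta["is_tumor"] = meta["is_tumor"].astype(bool)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out["is_tumor"] = out["is_tumor"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, tab-separated name, description, genes."""
    collection: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
        name = fields[0]
        if name in collection:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        genes = {g for g in fields[2:] if g}
        collection[name] = genes
    return collection


def write_gmt(collection: Mapping[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an undirected edge list TSV with two gene columns (header optional junk tolerated)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a gene->compound interaction table (TSV, columns gene, compound)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "compound" not in cols:
        raise ValueError("drug table must have 'gene' and 'compound' columns")
    out = df.rename(columns={cols["gene"]: "gene", cols["compound"]: "compound"})
    if out["gene"].isna().any() or out["compound"].isna().any():
        raise ValueError("drug table contains empty gene or compound entries")
    return out[["gene", "compound"]]


def read_scores(path: str | Path) -> tuple[pd.DataFrame, bool]:
    """Read a pathway x sample score TSV; returns (scores, normalized_flag)."""
    path = Path(path)
    normalized = False
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#normalized="):
            normalized = first.strip().split("=", 1)[1].lower() == "true"
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    return df, normalized


def write_scores(scores: pd.DataFrame, path: str | Path, normalized: bool) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"#normalized={'true' if normalized else 'false'}\n")
        scores.to_csv(fh, sep="\t", index_label="pathway", float_format="%.10g")


def write_truth(truth: Mapping[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: sorted(v) for k, v in truth.items()},
                                     indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())
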