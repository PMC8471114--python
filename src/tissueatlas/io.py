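"""Readers and writers for the pipeline's tab-separated interchange files."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .atlas import ExpressionAtlas

__all__ = [
    "read_matrix", "read_design", "read_atlas", "read_truth",
    "read_label_file", "read_gene_list",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV whose first column is ``gene_id``."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "tissue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design is missing columns {sorted(missing)}")
    return df[["sample_id", "tissue"]]


def read_atlas(expression_path, design_path) -> ExpressionAtlas:
    return ExpressionAtlas(
        expression=read_matrix(expression_path),
        design=read_design(design_path),
    )


def read_truth(path):
    """Load a planted-truth JSON written by :func:`tissueatlas.simulate.write_fixture`."""
    from .simulate import SyntheticTruth

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    genes = pd.DataFrame.from_dict(payload["genes"], orient="index")
    genes.index.name = "gene_id"
    return SyntheticTruth(
        genes=genes.sort_index(),
        modules=payload.get("modules", []),
        cliques=payload.get("cliques", []),
    )


def read_gene_list(path) -> list:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_label_file(path, name=None):
    from .labels import GeneLabelSet

    return GeneLabelSet(name=name or Path(path).stem, genes=read_gene_list(path))
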