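"""Readers and writers for the pipeline's plain-text formats.

Expression data travels as a series-matrix-style TSV: leading ``!``
metadata lines (``!Sample_id``, ``!Sample_group``) followed by a
genes-in-rows, samples-in-columns table headed ``ID_REF``.  Group labels
may instead come from a two-column sidecar TSV (sample, group).  Probe
maps are two-column TSVs (probe, gene).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .meta import ExpressionDataset


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!Sample_id\t" + "\t".join(dataset.matrix.columns) + "\n")
        fh.write("!Sample_group\t" + "\t".join(dataset.groups) + "\n")
    body = dataset.matrix.copy()
    body.index.name = "ID_REF"
    body.to_csv(path, sep="\t", mode="a")


def read_expression_tsv(
    path: str | Path,
    dataset_id: str | None = None,
    groups_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a series-matrix-style TSV, optionally with a sidecar group table."""
    path = Path(path)
    meta: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        skip = 0
        for line in fh:
            if not line.startswith("!"):
                break
            key, *values = line.rstrip("\n").split("\t")
            meta[key.lstrip("!")] = values
            skip += 1
    matrix = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    matrix.index = matrix.index.astype(str).str.upper()
    matrix.index.name = "gene"
    if groups_path is not None:
        sidecar = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        groups = sidecar.reindex(matrix.columns).astype(str)
    elif "Sample_group" in meta:
        groups = pd.Series(meta["Sample_group"], index=matrix.columns, name="group")
    else:
        raise ValueError(
            f"{path}: no !Sample_group line and no sidecar group table supplied"
        )
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem, matrix=matrix, groups=groups
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column probe -> gene TSV (header optional but recommended)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe, gene)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line, upper-cased; blank lines ignored."""
    return {
        line.strip().upper()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
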