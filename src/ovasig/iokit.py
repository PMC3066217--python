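"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: GCT #1.2 (expression), plain TSV with genes in rows,
CSV clinical tables, GMT gene-set collections, CLS two-class label files and
two-column TSV id maps.  Every loader validates into the shared data model;
round-tripping through a writer and loader preserves ids exactly and values
to full float precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    IdMap,
    ValidationError,
)

__all__ = [
    "load_expression",
    "write_expression",
    "load_clinical",
    "write_clinical",
    "load_gene_sets",
    "write_gene_sets",
    "load_id_map",
    "load_cls",
    "write_cls",
]


def _parse_numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at row "
                    f"{row!r}, column {col!r}"
                ) from None
        raise
    return values


def load_expression(path, format: str | None = None, log2_transform: bool = False) -> ExpressionMatrix:
    """Load an expression matrix from a GCT (#1.2) or TSV file.

    Parameters
    ----------
    format
        ``"gct"`` or ``"tsv"``; inferred from the file suffix when omitted.
    log2_transform
        Apply ``log2(x + 1)`` on load for raw-scale inputs.  Values are
        otherwise assumed to be on log2 scale already.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        em = _load_gct(path)
    elif format == "tsv":
        em = _load_tsv(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if log2_transform:
        if (em.values < 0).any():
            raise ValidationError(f"{path}: negative values cannot be log2(x+1) transformed")
        em = ExpressionMatrix(em.gene_ids, em.sample_ids, np.log2(em.values + 1.0), em.batch)
    return em


def _load_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValidationError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValidationError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype={0: str})
    if body.columns[0] != "Description":
        raise ValidationError(f"{path}: GCT requires a Description column")
    data = body.drop(columns=body.columns[0])
    if data.shape != (n_genes, n_samples):
        raise ValidationError(
            f"{path}: declared {n_genes} genes x {n_samples} samples but found "
            f"{data.shape[0]} x {data.shape[1]}"
        )
    values = _parse_numeric_block(data, path)
    return ExpressionMatrix(list(body.index.astype(str)), [str(c) for c in data.columns], values)


def _load_tsv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    values = _parse_numeric_block(df, path)
    return ExpressionMatrix(list(df.index.astype(str)), [str(c) for c in df.columns], values)


def write_expression(em: ExpressionMatrix, path, format: str | None = None,
                     descriptions: dict[str, str] | None = None) -> None:
    """Write a matrix as GCT #1.2 or TSV (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        desc = [(descriptions or {}).get(g, "") for g in em.gene_ids]
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.n_genes}\t{em.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(em.sample_ids) + "\n")
            for g, d, row in zip(em.gene_ids, desc, em.values):
                fh.write(g + "\t" + d + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(em.sample_ids) + "\n")
            for g, row in zip(em.gene_ids, em.values):
                fh.write(g + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def load_clinical(path) -> ClinicalTable:
    """Load a clinical CSV/TSV table (requires sample_id, os_months, event)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path) -> None:
    ct.data.reset_index().to_csv(path, index=False)


def load_gene_sets(path) -> GeneSetCollection:
    """Load a GMT file: one set per line — name, description, then gene ids."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc:
            fh.write("\t".join([name, gsc.descriptions.get(name, "")] + list(genes)) + "\n")


def load_id_map(path) -> IdMap:
    """Load a two-column TSV (source id, target gene id); header optional."""
    pairs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or not row[0].strip():
                continue
            if i == 0 and row[0].lower() in ("source", "source_id", "probe", "probeset"):
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}: id-map row needs source and target: {row}")
            pairs.append((row[0], row[1]))
    return IdMap.from_pairs(pairs)


def load_cls(path) -> tuple[list[str], list[str]]:
    """Load a categorical CLS label file.

    Returns ``(labels_per_sample, class_names)``.  The numeric body may use
    either class indices or the literal class names.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValidationError(f"{path}: CLS requires 3 non-empty lines")
    n, n_classes, _one = lines[0].split()
    names = lines[1].lstrip("#").split()
    if len(names) != int(n_classes):
        raise ValidationError(f"{path}: declared {n_classes} classes, header names {names}")
    tokens = lines[2].split()
    if len(tokens) != int(n):
        raise ValidationError(f"{path}: declared {n} samples but found {len(tokens)} labels")
    if all(t in names for t in tokens):
        labels = tokens
    else:
        labels = [names[int(t)] for t in tokens]
    return labels, names


def write_cls(labels, path) -> None:
    labels = [str(x) for x in labels]
    names = list(dict.fromkeys(labels))  # first-appearance order
    index = {name: i for i, name in enumerate(names)}
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(names)} 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(index[x]) for x in labels) + "\n")
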