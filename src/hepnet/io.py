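"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: tab-separated matrices/tables with ``NA`` (or an
empty cell) as the missing marker, standard 3+-field GMT files for gene-set
collections, and a two-column TSV for cell-type marker lists.  Floats are
written with pandas' shortest round-trip representation, so write -> read is
value-exact and repeated runs produce identical bytes.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np
import pandas as pd

from .containers import (
    REQUIRED_SHEET_COLUMNS,
    TRAIT_COLUMNS,
    AbundanceMatrix,
    GeneSetCollection,
    NetworkReference,
    SampleSheet,
    TraitTable,
)

NA_VALUES = ["", "NA"]


def _read_tsv(path, index_col=0):
    return pd.read_csv(
        path, sep="\t", index_col=index_col, na_values=NA_VALUES, keep_default_na=False, dtype=str
    )


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert string cells to float, reporting the first offending cell.

    Uses numpy's strtod (exact round-trip of the shortest float repr); the
    slower element-wise pass only runs to locate a bad cell.
    """
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        pass
    for row in df.index:
        for col in df.columns:
            cell = df.loc[row, col]
            if pd.isna(cell):
                continue
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {cell!r} at row {row!r}, column {col!r} in {path}"
                ) from None
    raise ValueError(f"could not parse numeric table {path}")


def read_abundance_matrix(path, scale: str = "raw") -> AbundanceMatrix:
    """Read a protein x sample TSV (first column = protein id) at a declared scale."""
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein id {dup!r} in {path}")
    return AbundanceMatrix(_coerce_numeric(df, path), scale)


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False, dtype=str)
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    df["is_gis"] = df["is_gis"].map({"True": True, "False": False, "1": True, "0": False})
    if df["is_gis"].isna().any():
        raise ValueError("is_gis column must contain True/False (or 1/0) values")
    # covariate columns: numeric where fully parseable, otherwise categorical strings
    for col in df.columns:
        if col in REQUIRED_SHEET_COLUMNS or col == "channel_label":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.notna().sum() >= df[col].notna().sum():
            df[col] = coerced
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = sheet.data.reset_index()
    df.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_trait_table(path) -> TraitTable:
    df = _read_tsv(path)
    df.index.name = "sample_id"
    return TraitTable(_coerce_numeric(df, path))


def write_trait_table(traits: TraitTable, path) -> None:
    df = traits.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_network_reference(membership_path, eigenprotein_path) -> NetworkReference:
    """Load a reference network from its two TSVs (membership; eigenproteins).

    The membership file has columns ``protein_id``, ``module_id`` and an
    optional ``module_label``.
    """
    mem = pd.read_csv(membership_path, sep="\t", na_values=NA_VALUES, keep_default_na=False, dtype=str)
    for col in ("protein_id", "module_id"):
        if col not in mem.columns:
            raise ValueError(f"missing column {col} in {membership_path}")
    labels = {}
    if "module_label" in mem.columns:
        labelled = mem.dropna(subset=["module_label"])
        labels = dict(zip(labelled["module_id"], labelled["module_label"]))
    eig = _coerce_numeric(_read_tsv(eigenprotein_path), eigenprotein_path)
    membership = pd.Series(mem["module_id"].to_numpy(), index=mem["protein_id"].to_numpy())
    return NetworkReference(membership, eig, labels)


def write_network_reference(ref: NetworkReference, membership_path, eigenprotein_path) -> None:
    mem = pd.DataFrame(
        {
            "protein_id": ref.membership.index,
            "module_id": ref.membership.to_numpy(),
            "module_label": [ref.module_labels.get(m, "") for m in ref.membership.to_numpy()],
        }
    )
    mem.to_csv(membership_path, sep="\t", index=False)
    eig = ref.eigenproteins.copy()
    eig.index.name = "module_id"
    eig.to_csv(eigenprotein_path, sep="\t", na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB gene1 TAB gene2 ...``"""
    collection = GeneSetCollection()
    opener = _io.StringIO(path.read()) if hasattr(path, "read") else open(path)
    with opener as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 tab-separated fields")
            set_id, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"line {lineno}: gene set {set_id!r} has no genes")
            collection.add(set_id, description, genes)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *gs.genes]) + "\n")


def read_marker_lists(path) -> dict:
    """Read cell-type marker lists from a two-column TSV (celltype, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("celltype", "gene"):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in {path}")
    markers: dict[str, list] = {}
    for celltype, gene in zip(df["celltype"], df["gene"]):
        markers.setdefault(celltype, []).append(gene.upper())
    return {ct: list(dict.fromkeys(genes)) for ct, genes in markers.items()}


def write_marker_lists(markers: dict, path) -> None:
    rows = [(ct, g) for ct in markers for g in markers[ct]]
    pd.DataFrame(rows, columns=["celltype", "gene"]).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a generic results table deterministically."""
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
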