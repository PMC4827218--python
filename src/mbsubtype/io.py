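"""Readers and writers for every external format the tool touches.

Formats are all plain text: GMT genesets (Broad convention: tab-separated,
no quoting, name / description / member genes), expression matrices as TSV
with a sample-name header row and gene symbols in the first column, label
and ortholog tables as two-column TSVs, and the prediction table described
in :func:`write_predictions`. Readers reject malformed input with the file
location rather than silently dropping or merging records.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .types import (
    SUBTYPES,
    ExpressionMatrix,
    GeneSetCollection,
    MBSubtypeError,
    validate_subtype,
)

if TYPE_CHECKING:  # pragma: no cover
    from .classify import PredictionResult


class ParseError(MBSubtypeError, ValueError):
    """Malformed input file; the message names the offending location."""


# ---------------------------------------------------------------------------
# GMT genesets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike, species: str) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated preserving first
    occurrence; trailing empty fields are ignored. A line with fewer than
    three fields or a repeated set name is an error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            for g in fields[2:]:
                if g and g not in members:
                    members.append(g)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = (desc, members)
    return GeneSetCollection(species=species, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    """Write a collection in GMT format; inverse of :func:`read_gmt`."""
    lines = []
    for name, (desc, members) in collection.sets.items():
        lines.append("\t".join([name, desc, *members]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample names, column 1 = gene symbols).

    Duplicate gene rows and non-numeric or missing cells are hard errors —
    probe collapsing and imputation are preprocessing concerns, not this
    reader's.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    values = np.empty(df.shape, dtype=float)
    cols = df.to_numpy()
    for j, sample in enumerate(df.columns):
        for i, cell in enumerate(cols[:, j]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[i]!r}, sample {sample!r}"
                ) from None
        if not np.all(np.isfinite(values[:, j])):
            i = int(np.argwhere(~np.isfinite(values[:, j]))[0][0])
            raise ParseError(
                f"{path}: non-finite value at gene {df.index[i]!r}, "
                f"sample {sample!r}"
            )
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an expression matrix as TSV; floats use shortest-exact repr."""
    df = expr.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Label tables and ortholog maps (two-column TSVs with header)
# ---------------------------------------------------------------------------

def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read ``sample_id<TAB>subtype`` with a header row; labels must be valid."""
    rows = _read_two_column(path)
    labels: dict[str, str] = {}
    for lineno, (sample, label) in rows:
        if sample in labels:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        try:
            labels[sample] = validate_subtype(label)
        except MBSubtypeError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return labels


def write_labels(labels: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tsubtype\n")
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_ortholog_map(path: str | os.PathLike) -> dict[str, str]:
    """Read ``mouse_symbol<TAB>human_symbol`` with a header row."""
    rows = _read_two_column(path)
    mapping: dict[str, str] = {}
    for lineno, (mouse, human) in rows:
        if not mouse or not human:
            raise ParseError(f"{path}:{lineno}: empty gene symbol")
        if mouse in mapping:
            raise ParseError(f"{path}:{lineno}: duplicate mouse symbol {mouse!r}")
        mapping[mouse] = human
    return mapping


def write_ortholog_map(mapping: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mouse_symbol\thuman_symbol\n")
        for mouse, human in mapping.items():
            fh.write(f"{mouse}\t{human}\n")


def _read_two_column(path: str | os.PathLike) -> list[tuple[int, tuple[str, str]]]:
    rows: list[tuple[int, tuple[str, str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if lineno == 1:
                continue  # header row
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            rows.append((lineno, (fields[0], fields[1])))
    return rows


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "sample_id",
    "predicted_subtype",
    "confidence_percent",
    *[f"vote_{s}" for s in SUBTYPES],
    "call_class",
]


def predictions_frame(results: "list[PredictionResult]") -> pd.DataFrame:
    """Tabulate prediction results into the canonical prediction table."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "predicted_subtype": r.predicted,
            "confidence_percent": r.confidence_percent,
        }
        for s in SUBTYPES:
            row[f"vote_{s}"] = r.votes.get(s, 0)
        row["call_class"] = r.call_class
        rows.append(row)
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions(
    results: "list[PredictionResult]", path: str | os.PathLike
) -> None:
    """Write the prediction table: one row per sample, vote counts per class,
    winning-vote percentage and the high_confidence / intermediate call."""
    df = predictions_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "confidence_percent": float}
    )
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing prediction columns {missing}")
    bad = ~df["call_class"].isin(["high_confidence", "intermediate"])
    if bad.any():
        raise ParseError(
            f"{path}: invalid call_class {df.loc[bad, 'call_class'].iloc[0]!r}"
        )
    return df[PREDICTION_COLUMNS]
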