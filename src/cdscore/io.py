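"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices travel as TSV (probesets x samples, header row of
sample IDs) or GCT v1.2; clinical tables as CSV/TSV keyed by sample_id;
probeset->gene maps as two-column TSV; candidate probeset lists as one ID
per line.  Frozen score models are JSON (see :mod:`cdscore.score`).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, ExpressionMatrix
from .exceptions import ParseError, ValidationError

_FLOAT_FMT = "%.12g"  # 12 significant digits: round-trips month-scale reals


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return "gct" if ext == ".gct" else "tsv"


def load_expression(path: str, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from TSV or GCT v1.2.

    TSV layout: first column probeset IDs, header row sample IDs.
    GCT v1.2 layout: ``#1.2`` line, ``<nrows>\\t<ncols>`` line, then a
    table with Name and Description columns followed by samples.
    """
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        if df.columns.size == 0:
            raise ParseError(f"{path}: header row has no sample IDs (line 1)")
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: expected '#1.2' on line 1, got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ParseError(f"{path}: expected '<nrows>\\t<ncols>' on line 2")
            nrows, ncols = (int(d) for d in dims)
            df = pd.read_csv(fh, sep="\t", keep_default_na=False)
        if df.columns[:2].tolist() != ["Name", "Description"]:
            raise ParseError(
                f"{path}: GCT header must start with 'Name\\tDescription' (line 3)"
            )
        df = df.set_index("Name").drop(columns="Description")
        df.index.name = None
        if df.shape != (nrows, ncols):
            raise ParseError(
                f"{path}: dimensions line says {nrows}x{ncols} but table is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric or missing value {df.iat[r, c]!r} at "
            f"probeset {df.index[r]!r} (row {r + 1}), sample {df.columns[c]!r} "
            f"(column {c + 1})"
        )
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        matrix.values.to_csv(path, sep="\t", index_label="probeset_id",
                             float_format=_FLOAT_FMT)
    elif fmt == "gct":
        nrows, ncols = matrix.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{nrows}\t{ncols}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def load_clinical(path: str, sep: str | None = None) -> ClinicalTable:
    """Load a clinical table from CSV or TSV (separator sniffed from the
    extension unless given).  Requires sample_id, os_time, os_event;
    every additional column is preserved as a covariate."""
    if sep is None:
        sep = "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","
    clinical.table.to_csv(path, sep=sep, index_label="sample_id",
                          float_format=_FLOAT_FMT)


def load_probeset_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping probeset ID -> gene symbol (no header, or a
    header line starting with 'probeset')."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and parts[0].lower().startswith("probeset"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def load_candidates(path: str) -> list[str]:
    """Candidate probeset list, one ID per line (first tab-separated field
    is used, so a probeset->gene map file is also accepted)."""
    out: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if not token or token.startswith("#"):
                continue
            if token not in seen:
                seen.add(token)
                out.append(token)
    return out


def class_labels_from_clinical(clinical: ClinicalTable) -> Mapping[str, str] | None:
    """Extract a class_label column from a clinical table if present."""
    if "class_label" in clinical.table.columns:
        return clinical.table["class_label"]
    return None
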