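"""Readers and writers for the package's plain-text file dialects.

* Expression matrix: TSV, first column ``gene_id``, one column per sample.
* Sample sheet: CSV with columns ``sample_id,group,replicate_index`` and an
  optional leading metadata line ``# scale=log2`` (or ``linear``) declaring
  the matrix scale; the scale is declared, never inferred, because a silent
  misread of the scale corrupts every downstream ratio.
* Electropherogram trace: CSV with header ``size_nt,fluorescence``.
* Exon-level table: TSV with columns ``gene_id,position_index,signal``.
* Cq table: CSV, first column ``gene_id``, replicate columns; the reference
  gene is named in a ``# reference=<gene>`` metadata line (default: first
  gene).

All files are UTF-8 with '.' as decimal separator, independent of locale.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import CqTable
from .errors import ParseError, ValidationError
from .matrix import ExpressionMatrix
from .quality import DEFAULT_WINDOW_MIN_NT, Electropherogram


def _read_metadata(path: Path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines of a file."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# Expression matrices + sample sheets
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Read and cross-validate an expression TSV and its sample sheet CSV."""
    matrix_path, sheet_path = Path(matrix_path), Path(sheet_path)

    meta = _read_metadata(sheet_path)
    scale = meta.get("scale", "log2")
    try:
        sheet = pd.read_csv(sheet_path, comment="#", dtype={"sample_id": str, "group": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{sheet_path}: {exc}") from exc
    required = {"sample_id", "group", "replicate_index"}
    if not required.issubset(sheet.columns):
        raise ParseError(f"{sheet_path}: needs columns {sorted(required)}, has {list(sheet.columns)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{sheet_path}: duplicate sample ids {dups}")

    try:
        values = pd.read_csv(
            matrix_path, sep="\t", index_col="gene_id", float_precision="round_trip"
        )
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: first column must be 'gene_id' ({exc})") from exc
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ParseError(f"{matrix_path}: duplicate gene ids {dups[:5]}")
    bad_cols = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if bad_cols:
        raise ParseError(f"{matrix_path}: non-numeric values in columns {bad_cols}")
    if values.isna().any().any():
        n = int(values.isna().sum().sum())
        raise ParseError(f"{matrix_path}: {n} missing/non-numeric cells")

    sheet_ids = set(sheet["sample_id"])
    matrix_ids = set(values.columns)
    missing = sorted(matrix_ids - sheet_ids)
    if missing:
        raise ValidationError(f"samples in matrix but not in sheet: {missing}")
    extra = sorted(sheet_ids - matrix_ids)
    if extra:
        raise ValidationError(f"samples in sheet but not in matrix: {extra}")

    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    pairing = dict(zip(sheet["sample_id"], sheet["replicate_index"].astype(int)))
    return ExpressionMatrix(values=values, scale=scale, groups=groups, pairing=pairing)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path, sheet_path: str | Path) -> None:
    """Write an expression matrix and its sample sheet (inverse of read_expression)."""
    matrix_path, sheet_path = Path(matrix_path), Path(sheet_path)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    with open(sheet_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "group", "replicate_index"])
        for s in matrix.sample_ids:
            writer.writerow([s, matrix.groups[s], matrix.pairing[s]])


# ---------------------------------------------------------------------------
# Electropherogram traces
# ---------------------------------------------------------------------------

def read_trace(
    path: str | Path, window_min_nt: float = DEFAULT_WINDOW_MIN_NT
) -> Electropherogram:
    """Read a trace CSV (header ``size_nt,fluorescence``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if not {"size_nt", "fluorescence"}.issubset(df.columns):
        raise ParseError(f"{path}: needs columns size_nt,fluorescence, has {list(df.columns)}")
    return Electropherogram(
        sizes_nt=df["size_nt"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        analysis_window=(window_min_nt, float("inf")),
    )


def write_trace(trace: Electropherogram, path: str | Path) -> None:
    pd.DataFrame({"size_nt": trace.sizes_nt, "fluorescence": trace.fluorescence}).to_csv(
        Path(path), index=False
    )


# ---------------------------------------------------------------------------
# Exon-level tables
# ---------------------------------------------------------------------------

def read_exon_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"gene_id", "position_index", "signal"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}, has {list(df.columns)}")
    return df


def write_exon_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

def read_cq_table(path: str | Path) -> CqTable:
    """Read a Cq CSV; the reference gene comes from ``# reference=`` metadata."""
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(
        path, comment="#", index_col="gene_id", float_precision="round_trip"
    )
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no replicate columns")
    ref = meta.get("reference", str(df.index[0]))
    return CqTable(values=df.astype(float), reference_gene=ref)


def write_cq_table(cq: CqTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# reference={cq.reference_gene}\n")
        cq.values.to_csv(fh)
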