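"""Plain-text readers and writers for every pipeline artefact.

Everything is tab-separated text: trace tables (one row per traced
point), expression matrices (first column ``gene_id``), sample-design
tables, per-contrast statistics, category assignments and candidate
reports; nested count summaries go to JSON.  A minimal reader for the GEO
series-matrix format (tab-delimited with ``!``-prefixed metadata lines)
lets a deposited expression series be ingested directly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult, ExpressionStudy
from .morphometrics import RootTrace


class ParseError(ValueError):
    """Raised for malformed input files; message names file and problem."""


TRACE_COLUMNS = [
    "trace_id",
    "ecotype",
    "angle_gp",
    "replicate",
    "point_index",
    "x_mm",
    "y_mm",
]


def read_traces(path: str | Path) -> list[RootTrace]:
    """Read a trace table (TSV or CSV by extension).

    Required columns: trace_id, ecotype, angle_gp, replicate, point_index,
    x_mm, y_mm; optional view_flipped.  Points are sorted by point_index
    within each trace.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no traces (empty file)") from None
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: no traces")
    traces = []
    for tid, sub in df.groupby("trace_id", sort=True):
        idx = sub["point_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            first_bad = int(np.flatnonzero(np.diff(idx) <= 0)[0])
            line = int(sub.index[first_bad + 1]) + 2  # header + 0-based
            raise ParseError(
                f"{path}: duplicate/unsorted point_index for trace {tid!r}"
                f" near line {line}"
            )
        flipped = bool(sub["view_flipped"].iloc[0]) if "view_flipped" in sub else False
        traces.append(
            RootTrace(
                trace_id=str(tid),
                ecotype=str(sub["ecotype"].iloc[0]),
                angle_gp=int(sub["angle_gp"].iloc[0]),
                replicate=int(sub["replicate"].iloc[0]),
                points=sub[["x_mm", "y_mm"]].to_numpy(dtype=float),
                view_flipped=flipped,
            )
        )
    return traces


def write_traces(traces: list[RootTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "ecotype": tr.ecotype,
                    "angle_gp": tr.angle_gp,
                    "replicate": tr.replicate,
                    "point_index": i,
                    "x_mm": x,
                    "y_mm": y,
                    "view_flipped": tr.view_flipped,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene_id, remaining columns sample IDs."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene IDs {dups[:5]}")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "ecotype", "angle_gp", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df.set_index("sample_id")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.rename_axis("sample_id").to_csv(path, sep="\t")


def read_study(matrix_path: str | Path, design_path: str | Path) -> ExpressionStudy:
    matrix = read_expression_matrix(matrix_path)
    design = read_design(design_path)
    try:
        return ExpressionStudy(values=matrix, design=design)
    except ValueError as exc:
        raise ParseError(f"{matrix_path} / {design_path}: {exc}") from exc


def write_contrast(result: ContrastResult, path: str | Path) -> None:
    result.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_contrast(path: str | Path, contrast_id: str | None = None) -> ContrastResult:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    for col in ("sig", "sig_fdr"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if contrast_id is None:
        contrast_id = Path(path).stem
    return ContrastResult(contrast_id=contrast_id, table=df)


def write_table(df: pd.DataFrame, path: str | Path, index_name: str | None = None) -> None:
    if index_name is not None:
        df = df.rename_axis(index_name)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def read_geo_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Parse a GEO series-matrix file.

    Metadata lines start with '!'; the expression table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` with
    an ID_REF column of probe/gene identifiers.  Returns
    (matrix indexed by ID_REF, metadata dict of lists).
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                meta.setdefault(key, []).extend(values)
    if not table_lines:
        raise ParseError(f"{path}: no series_matrix table section")
    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t")
    first = df.columns[0]
    df[first] = df[first].astype(str).str.strip('"')
    df = df.rename(columns={first: "gene_id"}).set_index("gene_id")
    return df, meta
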