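"""Reading, validating, transforming and writing cytometry expression tables.

The central container is :class:`ExpressionTable`: one row per cell, one
column per marker, plus ``cell_id`` and ``sample_id`` identifier columns and
optional ``batch_id`` / ``cell_type`` / ``cluster_id`` annotations. Input is
either a delimited text file (CSV, header required) or an FCS 3.0/3.1 file.
Marker intensities are expected on the arcsinh scale; :func:`arcsinh_transform`
applies ``asinh(x / cofactor)`` for raw data (cofactor 5 is conventional for
mass cytometry, 150 for flow cytometry).

FCS support is read-only and deliberately minimal: list-mode files with
float (``$DATATYPE F``/``D``) events, no compensation or spillover handling —
the pipeline assumes cleaned, pre-gated input.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ID_COLUMNS = ("cell_id", "sample_id")
OPTIONAL_COLUMNS = ("batch_id", "cell_type", "cluster_id")

EXPRESSION_FILENAME = "supercell_expression.csv"
MAP_FILENAME = "cell_supercell_map.csv"


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class IntegrityError(ValueError):
    """Table content violates an invariant (duplicate ids, non-finite values)."""


@dataclass
class ExpressionTable:
    """Per-cell marker expression with identifiers and optional annotations.

    Parameters
    ----------
    data
        One row per cell. Must contain ``cell_id`` (unique), ``sample_id``
        (non-empty) and every column named in ``markers``.
    markers
        Names of the marker columns, in order. Any column not listed here and
        not an identifier/annotation column (e.g. Time, Event_length) is
        carried along untouched but ignored by the pipeline.
    """

    data: pd.DataFrame
    markers: list[str]

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        validate_table(self.data, self.markers)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        """Distinct sample ids in first-appearance order."""
        return list(dict.fromkeys(self.data["sample_id"]))

    def marker_matrix(self) -> np.ndarray:
        return self.data[self.markers].to_numpy(dtype=float)

    def restrict_to_sample(self, sample_id: str) -> "ExpressionTable":
        sub = self.data[self.data["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"sample {sample_id!r} not present in table")
        return ExpressionTable(sub.reset_index(drop=True), self.markers)


def validate_table(data: pd.DataFrame, markers: list[str]) -> None:
    if not markers:
        raise SchemaError("at least one marker column is required")
    missing = [c for c in (*ID_COLUMNS, *markers) if c not in data.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    dup = data["cell_id"][data["cell_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(
            f"duplicate cell_id values: {sorted(set(dup.astype(str)))[:10]}"
        )
    sid = data["sample_id"].astype(str)
    if (sid == "").any() or data["sample_id"].isna().any():
        bad = data.index[(sid == "") | data["sample_id"].isna()].tolist()
        raise IntegrityError(f"empty sample_id in rows {bad[:10]}")
    vals = data[markers]
    numeric = vals.apply(pd.to_numeric, errors="coerce")
    bad_mask = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad_mask.any():
        rows, cols = np.nonzero(bad_mask)
        offending = [
            (int(data.index[r]), markers[c]) for r, c in zip(rows[:10], cols[:10])
        ]
        raise IntegrityError(
            f"non-finite or non-numeric marker values at (row, column): {offending}"
        )


# ---------------------------------------------------------------------------
# Delimited input
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    format: str = "delimited",
    column_map: dict[str, str] | None = None,
    markers: list[str] | None = None,
    sample_id: str | None = None,
) -> ExpressionTable:
    """Read an :class:`ExpressionTable` from a CSV or FCS file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"delimited"`` (CSV with header) or ``"fcs"`` (FCS 3.0/3.1).
    column_map
        Optional renaming applied to the file's columns before validation,
        e.g. ``{"sample": "sample_id"}``.
    markers
        Marker columns to use. Defaults to every non-identifier,
        non-annotation column.
    sample_id
        For FCS input (which carries no sample column): sample id to assign;
        defaults to the file stem. Cell ids are synthesised as
        ``<sample_id>:<row index>`` (0-based, event order preserved).
    """
    path = Path(path)
    if format == "delimited":
        df = pd.read_csv(path)
    elif format == "fcs":
        df = _read_fcs_events(path)
        sid = sample_id if sample_id is not None else path.stem
        df.insert(0, "sample_id", sid)
        df.insert(0, "cell_id", [f"{sid}:{i}" for i in range(len(df))])
    else:
        raise ValueError(f"unknown format {format!r}; expected 'delimited' or 'fcs'")
    if column_map:
        df = df.rename(columns=column_map)
    if format == "delimited" and "cell_id" not in df.columns:
        # deterministic synthesis from sample and within-sample row order
        if "sample_id" not in df.columns:
            raise SchemaError("missing required columns: ['sample_id']")
        idx = df.groupby("sample_id", sort=False).cumcount()
        df.insert(0, "cell_id", df["sample_id"].astype(str) + ":" + idx.astype(str))
    if markers is None:
        reserved = set(ID_COLUMNS) | set(OPTIONAL_COLUMNS)
        markers = [c for c in df.columns if c not in reserved]
    return ExpressionTable(df, markers)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 (read-only, list mode, float data)
# ---------------------------------------------------------------------------


def _read_fcs_text_segment(raw: bytes, begin: int, end: int) -> dict[str, str]:
    seg = raw[begin : end + 1]
    if not seg:
        raise SchemaError("FCS TEXT segment is empty")
    delim = seg[0:1]
    # keyword/value pairs are delimiter-separated; escaped (doubled) delimiters
    # are not supported by this minimal reader
    parts = seg[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise SchemaError("FCS TEXT segment has an odd number of tokens")
    out: dict[str, str] = {}
    for k, v in zip(parts[::2], parts[1::2]):
        out[k.decode("utf-8", "replace").strip().upper()] = v.decode(
            "utf-8", "replace"
        ).strip()
    return out


def _read_fcs_events(path: Path) -> pd.DataFrame:
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise SchemaError(f"unsupported FCS version {version!r} (need FCS 3.0/3.1)")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    data_begin = int(raw[26:34])
    data_end = int(raw[34:42])
    kw = _read_fcs_text_segment(raw, text_begin, text_end)
    if data_begin == 0:
        data_begin = int(kw["$BEGINDATA"])
    if data_end == 0:
        data_end = int(kw["$ENDDATA"])
    if kw.get("$MODE", "L").upper() != "L":
        raise SchemaError(f"unsupported FCS $MODE {kw.get('$MODE')!r} (need list mode)")
    dtype = kw.get("$DATATYPE", "F").upper()
    if dtype not in ("F", "D"):
        raise SchemaError(f"unsupported FCS $DATATYPE {dtype!r} (need F or D)")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        order = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        order = ">"
    else:
        raise SchemaError(f"unsupported FCS $BYTEORD {byteord!r}")
    width = 4 if dtype == "F" else 8
    expected = n_par * n_tot * width
    data = raw[data_begin : data_end + 1]
    if len(data) < expected:
        raise IntegrityError(
            f"FCS DATA segment holds {len(data)} bytes; "
            f"{expected} required for {n_tot} events x {n_par} channels"
        )
    arr = np.frombuffer(
        data[:expected], dtype=np.dtype(f"{order}f{width}")
    ).reshape(n_tot, n_par)
    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return pd.DataFrame(np.asarray(arr, dtype=float), columns=names)


# ---------------------------------------------------------------------------
# ArcSinh transform
# ---------------------------------------------------------------------------


@dataclass
class TransformSpec:
    """Which markers to transform and how.

    ``method="arcsinh"`` replaces each value x by asinh(x / cofactor);
    ``method="none"`` leaves the table untouched (for pre-transformed input).
    """

    method: str = "arcsinh"
    cofactor: float = 5.0
    markers: list[str] | None = None  # None = all markers of the table

    def __post_init__(self) -> None:
        if self.method not in ("arcsinh", "none"):
            raise ValueError(f"unknown transform method {self.method!r}")
        if self.cofactor <= 0:
            raise ValueError(f"cofactor must be > 0, got {self.cofactor}")


def arcsinh_transform(table: ExpressionTable, spec: TransformSpec) -> ExpressionTable:
    """Apply ``asinh(x / cofactor)`` to the selected marker columns.

    Untouched columns are copied bit-identically. Strictly monotone per
    marker, so ranks within a marker are preserved.
    """
    targets = spec.markers if spec.markers is not None else table.markers
    unknown = [m for m in targets if m not in table.markers]
    if unknown:
        raise KeyError(f"unknown marker names: {unknown}")
    if spec.method == "none":
        return ExpressionTable(table.data.copy(), table.markers)
    df = table.data.copy()
    for m in targets:
        df[m] = np.arcsinh(df[m].to_numpy(dtype=float) / spec.cofactor)
    return ExpressionTable(df, table.markers)


# ---------------------------------------------------------------------------
# Outputs: supercell expression matrix and cell-supercell map
# ---------------------------------------------------------------------------


def write_outputs(expr, partition, out_dir: str | Path) -> dict[str, Path]:
    """Write the supercell expression matrix and the cell-supercell map.

    ``supercell_expression.csv`` has header
    ``supercell_id,sample_id,n_cells,<markers...>``;
    ``cell_supercell_map.csv`` has header ``cell_id,sample_id,supercell_id``.
    Re-reading with :func:`read_outputs` reproduces the inputs.
    """
    expr_ids = set(expr.data["supercell_id"])
    map_ids = set(partition.mapping["supercell_id"])
    if not map_ids <= expr_ids:
        raise IntegrityError(
            f"map references supercell ids absent from expression: "
            f"{sorted(map_ids - expr_ids)[:10]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr_path = out_dir / EXPRESSION_FILENAME
    map_path = out_dir / MAP_FILENAME
    expr.data.to_csv(expr_path, index=False, float_format="%.17g")
    partition.mapping.to_csv(map_path, index=False)
    return {"expression": expr_path, "map": map_path}


def read_outputs(out_dir: str | Path):
    """Read back files produced by :func:`write_outputs`."""
    from .core import SupercellExpression, SupercellPartition

    out_dir = Path(out_dir)
    expr_df = pd.read_csv(out_dir / EXPRESSION_FILENAME)
    map_df = pd.read_csv(out_dir / MAP_FILENAME, dtype=str)
    markers = [
        c for c in expr_df.columns if c not in ("supercell_id", "sample_id", "n_cells")
    ]
    return (
        SupercellExpression(expr_df, markers),
        SupercellPartition(map_df),
    )
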