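"""Expression-matrix, annotation and metadata I/O.

All downstream modules work on a canonical in-memory representation: a
feature x sample :class:`ExpressionMatrix` holding log2 intensities in a
pandas DataFrame (rows = features, columns = samples), plus optional
:class:`FeatureAnnotation` and :class:`SampleMetadata` tables.

Two on-disk dialects are supported:

* ``tsv`` — plain tab-separated matrix, first column feature id, header row
  sample ids, '.' decimal.
* ``series_matrix_like`` — a text file containing a block delimited by
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` (the layout
  GEO uses for series-matrix exports); everything outside the block is
  ignored.

The scale of input values is never changed silently.  On read the scale is
inferred from the value range (see :func:`infer_scale_tag`) and recorded in
``scale_tag``; callers may request an explicit log2 transform via
:meth:`ExpressionMatrix.to_log2`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

ScaleTag = Literal["log2", "linear", "unknown"]

CONTROL_CLASSES = (
    "none",
    "three_prime",
    "five_prime",
    "spike_polyA",
    "spike_hyb",
    "border_positive",
    "border_negative",
)


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Log2 feature x sample intensity matrix.

    Parameters
    ----------
    data
        DataFrame with unique feature ids as index and unique sample ids as
        columns; values are intensities (log2 units unless ``scale_tag``
        says otherwise).
    scale_tag
        One of ``log2``, ``linear``, ``unknown``.
    """

    data: pd.DataFrame
    scale_tag: ScaleTag = "log2"

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise MatrixFormatError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        if any(c is None or (isinstance(c, str) and not c) for c in cols):
            raise MatrixFormatError("missing sample identifier in header")
        if self.scale_tag not in ("log2", "linear", "unknown"):
            raise ValueError(f"invalid scale_tag: {self.scale_tag!r}")

    # -- convenience views -------------------------------------------------
    @property
    def features(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_vector(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale_tag)

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy, applying log2(x+1) to linear data.

        Applied only on explicit request; ``unknown`` data is returned
        unchanged with a warning (treated as log2 by convention).
        """
        if self.scale_tag == "log2":
            return self
        if self.scale_tag == "linear":
            return ExpressionMatrix(np.log2(self.data + 1.0), "log2")
        warnings.warn("scale_tag is 'unknown'; treating values as log2 without transform")
        return ExpressionMatrix(self.data.copy(), "log2")


@dataclass
class FeatureAnnotation:
    """Per-feature annotation: gene mapping and control-feature classes.

    ``table`` columns: ``feature_id``, optional ``gene_symbol``,
    ``control_class`` in :data:`CONTROL_CLASSES`, and ``control_group_label``
    (required for 3'/5' pair members, e.g. ``GAPDH``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "feature_id" not in t.columns:
            raise ValueError("annotation requires a feature_id column")
        if t["feature_id"].duplicated().any():
            dup = t.loc[t["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValueError(f"duplicate feature_id in annotation: {dup!r}")
        if "control_class" not in t.columns:
            t = t.assign(control_class="none")
        bad = set(t["control_class"].unique()) - set(CONTROL_CLASSES)
        if bad:
            raise ValueError(f"unknown control_class values: {sorted(bad)}")
        if "control_group_label" not in t.columns:
            t = t.assign(control_group_label="")
        t["control_group_label"] = t["control_group_label"].fillna("")
        pair = t["control_class"].isin(["three_prime", "five_prime"])
        missing = pair & (t["control_group_label"] == "")
        if missing.any():
            fid = t.loc[missing, "feature_id"].iloc[0]
            raise ValueError(
                f"3'/5' control feature {fid!r} lacks a control_group_label"
            )
        self.table = t.set_index("feature_id", drop=False)

    def features_of_class(self, control_class: str) -> list:
        return list(self.table.loc[self.table["control_class"] == control_class, "feature_id"])

    def pair_labels(self) -> list[str]:
        pair = self.table["control_class"].isin(["three_prime", "five_prime"])
        return sorted(self.table.loc[pair, "control_group_label"].unique())


@dataclass
class SampleMetadata:
    """Sample-level metadata: group, subject, time point, pairing key."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group_label")
    OPTIONAL = ("subject_id", "time_point", "pairing_key")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"metadata requires a {col} column")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
        for col in self.OPTIONAL:
            if col not in t.columns:
                t[col] = pd.NA
        if t["time_point"].notna().any():
            tp = pd.to_numeric(t["time_point"], errors="coerce")
            if (tp.dropna() < 0).any():
                raise ValueError("time_point must be non-negative")
            t["time_point"] = tp
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "group_label"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# scale inference
# ---------------------------------------------------------------------------

def infer_scale_tag(values: np.ndarray) -> ScaleTag:
    """Infer whether a matrix is log2 or linear scale from its value range.

    Rule: max <= 30 -> log2; min >= 0 and max > 100 -> linear; anything else
    is ambiguous -> ``unknown`` (downstream code treats it as log2 and the
    reader warns).
    """
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return "unknown"
    vmax = float(finite.max())
    vmin = float(finite.min())
    if vmax <= 30.0:
        return "log2"
    if vmin >= 0.0 and vmax > 100.0:
        return "linear"
    return "unknown"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_matrix_lines(lines: list[str], first_line_no: int) -> pd.DataFrame:
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    n_cols = len(sample_ids)
    feat_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for offset, line in enumerate(lines[1:], start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) - 1 != n_cols:
            raise MatrixFormatError(
                f"ragged row at line {first_line_no + offset}: expected "
                f"{n_cols} values, got {len(parts) - 1}"
            )
        fid = parts[0].strip().strip('"')
        if fid in seen:
            raise MatrixFormatError(f"duplicate feature id: {fid!r}")
        seen.add(fid)
        feat_ids.append(fid)
        rows.append([_parse_value(v) for v in parts[1:]])
    data = pd.DataFrame(rows, index=feat_ids, columns=sample_ids, dtype=float)
    return data


def _parse_value(token: str) -> float:
    token = token.strip().strip('"')
    if token in ("", "NA", "NaN", "nan", "null"):
        return np.nan
    return float(token)


def read_matrix(
    path: str | Path,
    dialect: Literal["tsv", "series_matrix_like"] = "tsv",
    scale_tag: ScaleTag | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix; rows = features after read, always.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``tsv`` or ``series_matrix_like``.
    scale_tag
        Explicit scale declaration; inferred from the value range when None.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines(keepends=True)
    if dialect == "tsv":
        lines, first = raw_lines, 1
    elif dialect == "series_matrix_like":
        begin = end = None
        for i, line in enumerate(raw_lines):
            if line.startswith("!series_matrix_table_begin"):
                begin = i
            elif line.startswith("!series_matrix_table_end"):
                end = i
        if begin is None or end is None or end <= begin + 1:
            raise MatrixFormatError(
                "no !series_matrix_table_begin/end block found in "
                f"{path.name}"
            )
        lines, first = raw_lines[begin + 1 : end], begin + 2
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not lines:
        raise MatrixFormatError(f"empty matrix file: {path}")
    data = _parse_matrix_lines(lines, first)
    n_missing = int(data.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{path.name}: {n_missing} missing values recorded")
    if scale_tag is None:
        scale_tag = infer_scale_tag(data.to_numpy())
        if scale_tag == "unknown":
            warnings.warn(
                f"{path.name}: value range is ambiguous; scale_tag set to "
                "'unknown' and values treated as log2"
            )
    return ExpressionMatrix(data, scale_tag)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix as TSV with full repr precision (lossless round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(str(s) for s in matrix.samples) + "\n")
        for fid, row in zip(matrix.features, matrix.data.to_numpy()):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_annotation(path: str | Path) -> FeatureAnnotation:
    return FeatureAnnotation(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


def write_annotation(annotation: FeatureAnnotation, path: str | Path) -> Path:
    annotation.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> Path:
    metadata.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def align_metadata(
    matrix: ExpressionMatrix, metadata: SampleMetadata
) -> tuple[ExpressionMatrix, SampleMetadata, dict]:
    """Restrict matrix and metadata to shared samples, matrix order.

    Returns the aligned pair plus a report dict listing dropped ids on each
    side.  Zero overlap is a hard error.
    """
    matrix_ids = matrix.samples
    meta_ids = set(metadata.sample_ids)
    shared = [s for s in matrix_ids if s in meta_ids]
    if not shared:
        raise ValueError("matrix and metadata share no sample ids")
    dropped_matrix = [s for s in matrix_ids if s not in meta_ids]
    dropped_meta = sorted(meta_ids - set(matrix_ids))
    aligned_matrix = matrix.subset_samples(shared)
    aligned_meta = metadata.subset(shared)
    report = {"dropped_from_matrix": dropped_matrix, "dropped_from_metadata": dropped_meta}
    return aligned_matrix, aligned_meta, report
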