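"""Readers and writers for the tabular formats the tool touches.

Two input dialects are supported:

* a feature-table TSV (features in rows, samples in columns) paired with a
  sample-metadata TSV holding class/subclass columns, and
* the "classic" single-TSV dialect where designated leading rows carry the
  class, optional subclass, and optional sample-id labels.

All files are tab-separated UTF-8 with no quoting. Missing abundance cells
("NA" or empty) are errors: the rank-based method has no missing-data
semantics and silent imputation would change rank statistics.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    AbundanceTable,
    MarkerRecord,
    MarkerResult,
    SampleGroups,
    ValidationError,
    validate_inputs,
)

__all__ = [
    "read_feature_table",
    "read_lefse_classic",
    "parse_lineage",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = ("features", "scores")


def _to_numeric_matrix(df: pd.DataFrame, source: str) -> np.ndarray:
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"{source}: missing abundance value in feature {row!r}")
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{source}: non-numeric abundance cell ({exc})") from None
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{source}: non-finite abundance value")
    return values


def read_feature_table(
    table_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    class_column: str,
    subclass_column: Optional[str] = None,
    reference_level: Optional[str] = None,
) -> tuple[AbundanceTable, SampleGroups]:
    """Read a feature-table TSV plus a sample-metadata TSV.

    The feature table has feature ids in the first column and sample ids in
    the header; the metadata file has sample ids in its first column plus
    named label columns. Samples in the table must all appear in the
    metadata; extra metadata rows are ignored.
    """
    raw = pd.read_csv(table_path, sep="\t", header=0, index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{table_path}: duplicate feature id {dup!r}")
    values = _to_numeric_matrix(raw, str(table_path))
    table = AbundanceTable(values, [str(i) for i in raw.index], [str(c) for c in raw.columns])

    meta = pd.read_csv(metadata_path, sep="\t", header=0, index_col=0, dtype=str)
    if class_column not in meta.columns:
        raise ValidationError(
            f"{metadata_path}: missing class column {class_column!r} "
            f"(available: {list(meta.columns)})"
        )
    if subclass_column is not None and subclass_column not in meta.columns:
        raise ValidationError(f"{metadata_path}: missing subclass column {subclass_column!r}")
    meta.index = meta.index.map(str)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(
            f"{metadata_path}: no metadata for sample(s) {missing[:5]}"
        )
    meta = meta.loc[table.sample_ids]
    classes = meta[class_column]
    if classes.isna().any():
        raise ValidationError(f"{metadata_path}: missing class label")
    groups = SampleGroups(
        sample_ids=table.sample_ids,
        class_labels=[str(c) for c in classes],
        subclass_labels=(
            [str(s) for s in meta[subclass_column]] if subclass_column else None
        ),
        reference_level=reference_level,
    )
    return validate_inputs(table, groups)


def read_lefse_classic(
    path: str | os.PathLike,
    class_row: int = 0,
    subclass_row: Optional[int] = None,
    id_row: Optional[int] = None,
    reference_level: Optional[str] = None,
) -> tuple[AbundanceTable, SampleGroups]:
    """Read the classic single-TSV dialect.

    Row indices are 0-based positions in the file; each row's first cell is
    its name and the remaining cells are per-sample values. Rows not named
    by ``class_row``/``subclass_row``/``id_row`` are features.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    if width < 2:
        raise ValidationError(f"{path}: need at least one sample column")
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValidationError(
                f"{path}: row {i} ({row[0]!r}) has {len(row)} columns, expected {width}"
            )
    n_samples = width - 1
    label_rows = {class_row}
    if class_row >= len(rows):
        raise ValidationError(f"{path}: class_row {class_row} out of range")
    class_labels = rows[class_row][1:]
    subclass_labels = None
    if subclass_row is not None:
        if subclass_row >= len(rows):
            raise ValidationError(f"{path}: subclass_row {subclass_row} out of range")
        subclass_labels = rows[subclass_row][1:]
        label_rows.add(subclass_row)
    if id_row is not None:
        if id_row >= len(rows):
            raise ValidationError(f"{path}: id_row {id_row} out of range")
        sample_ids = rows[id_row][1:]
        label_rows.add(id_row)
    else:
        sample_ids = [f"sample_{j + 1}" for j in range(n_samples)]

    feature_ids: list[str] = []
    feature_values: list[list[float]] = []
    for i, row in enumerate(rows):
        if i in label_rows:
            continue
        name, cells = row[0], row[1:]
        if name in feature_ids:
            raise ValidationError(f"{path}: duplicate feature id {name!r}")
        try:
            feature_values.append([float(c) for c in cells])
        except ValueError:
            raise ValidationError(
                f"{path}: non-numeric abundance cell in feature row {name!r}"
            ) from None
        feature_ids.append(name)
    if not feature_ids:
        raise ValidationError(f"{path}: no feature rows found")

    table = AbundanceTable(np.array(feature_values, dtype=float), feature_ids, sample_ids)
    groups = SampleGroups(
        sample_ids=sample_ids,
        class_labels=class_labels,
        subclass_labels=subclass_labels,
        reference_level=reference_level,
    )
    return validate_inputs(table, groups)


def parse_lineage(feature_id: str, separator: str = "|") -> list[str]:
    """Split a lineage-style feature id into root-to-leaf rank names.

    Rank prefixes (``k__``, ``p__``, ...) are preserved verbatim. Empty
    strings and empty components are errors.
    """
    if feature_id == "":
        raise ValidationError("empty feature id cannot be parsed as a lineage")
    parts = feature_id.split(separator)
    if any(p == "" for p in parts):
        raise ValidationError(f"lineage {feature_id!r} contains an empty component")
    return parts


def write_results(result: MarkerResult, path: str | os.PathLike) -> None:
    """Write a marker table as TSV with the exact header ``features\\tscores``.

    Scores are rendered with enough digits for a faithful read-back; the
    file is written atomically (temp file + rename) so a failed write never
    leaves a partial output behind.
    """
    tmp = f"{path}.tmp"
    try:
        with open(tmp, "w", encoding="utf-8") as fh:
            fh.write("features\tscores\n")
            for rec in result.records:
                fh.write(f"{rec.feature_id}\t{rec.score:.10g}\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def read_results(path: str | os.PathLike) -> MarkerResult:
    """Read back a marker table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"features": str})
    if tuple(df.columns) != RESULT_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {RESULT_COLUMNS}, found {tuple(df.columns)}"
        )
    return MarkerResult(
        [MarkerRecord(str(f), float(s)) for f, s in zip(df["features"], df["scores"])]
    )
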