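"""Read, write and transform the long-format expression template.

The template is a plain TSV/CSV file with one measured value per row and
a commented metadata header::

    #project_name: flower atlas
    #subjects: Arabidopsis thaliana flower
    gene_id  spatial_id  condition  time  replicate  value
    AP1      sepal       default    21d   1          8.13

Columns may appear in any order; ``condition``, ``time`` and
``replicate`` are optional and default to ``"default"``, ``""`` and
``1``.  A missing value cell (empty, ``NA``, ``NaN``, ``null``) is an
explicit missing state and is never coerced to zero.  A spreadsheet
(.xlsx) with the same header is accepted as a convenience dialect and is
translated to the same in-memory model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from atlaspaint.errors import TemplateError

#: Canonical column order used when writing.
COLUMNS = ["gene_id", "spatial_id", "condition", "time", "replicate", "value"]

#: Columns that must be present in every template.
MANDATORY = ["gene_id", "spatial_id", "value"]

_MISSING_TOKENS = {"", "na", "nan", "null", "none", "missing"}


@dataclass(frozen=True)
class ExpressionRecord:
    """One measured (or missing) expression value for a gene in a segment."""

    gene_id: str
    spatial_id: str
    condition: str = "default"
    time: str = ""
    replicate: int = 1
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id.strip():
            raise TemplateError("gene_id must be non-empty")
        if not self.spatial_id.strip():
            raise TemplateError("spatial_id must be non-empty")
        if self.value is not None and not math.isfinite(self.value):
            raise TemplateError(
                f"value for {self.gene_id}/{self.spatial_id} is not finite"
            )


@dataclass
class ExperimentMetadata:
    """Free-form experiment annotation carried in the template header."""

    project_name: str = ""
    subjects: str = ""
    conditions: list[str] = field(default_factory=list)
    source_note: str = ""


class ExpressionDataset:
    """In-memory twin of the template: metadata plus a record table.

    Records live in a :class:`pandas.DataFrame` with the canonical
    columns; ``value`` uses NaN for the explicit missing state.
    """

    def __init__(self, frame: pd.DataFrame, metadata: ExperimentMetadata | None = None):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise TemplateError(f"record frame lacks columns {missing}")
        frame = frame[COLUMNS].copy()
        frame["gene_id"] = frame["gene_id"].astype(str).str.strip()
        frame["spatial_id"] = frame["spatial_id"].astype(str).str.strip()
        frame["condition"] = frame["condition"].astype(str)
        frame["time"] = frame["time"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        frame["value"] = pd.to_numeric(frame["value"], errors="raise").astype(float)
        if (frame["gene_id"] == "").any() or (frame["spatial_id"] == "").any():
            raise TemplateError("empty gene_id or spatial_id in records")
        bad = np.isinf(frame["value"].to_numpy())
        if bad.any():
            raise TemplateError(f"non-finite value in row {int(np.argmax(bad))}")
        dupes = frame.duplicated(subset=COLUMNS[:5], keep=False)
        if dupes.any():
            first = frame[dupes].iloc[0]
            raise TemplateError(
                "duplicate record for (gene, spatial, condition, time, replicate) = "
                f"({first.gene_id}, {first.spatial_id}, {first.condition}, "
                f"{first.time}, {first.replicate})"
            )
        self.frame = frame.reset_index(drop=True)
        if metadata is None:
            metadata = ExperimentMetadata()
        metadata.conditions = self.conditions()
        self.metadata = metadata

    # -- views -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[ExpressionRecord]:
        for row in self.frame.itertuples(index=False):
            yield ExpressionRecord(
                gene_id=row.gene_id,
                spatial_id=row.spatial_id,
                condition=row.condition,
                time=row.time,
                replicate=int(row.replicate),
                value=None if pd.isna(row.value) else float(row.value),
            )

    def genes(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique())

    def spatial_ids(self) -> list[str]:
        return sorted(self.frame["spatial_id"].unique())

    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def gene_condition_pairs(self) -> list[tuple[str, str]]:
        pairs = self.frame[["gene_id", "condition"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))

    def value_for(
        self, gene_id: str, spatial_id: str, condition: str = "default", time: str | None = None
    ) -> float | None:
        """Aggregated value for one cell, or None when absent/missing."""
        f = self.frame
        sel = (f["gene_id"] == gene_id) & (f["spatial_id"] == spatial_id) & (
            f["condition"] == condition
        )
        if time is not None:
            sel &= f["time"] == time
        vals = f.loc[sel, "value"].dropna()
        if vals.empty:
            return None
        return float(vals.mean())

    def is_aggregated(self) -> bool:
        return not self.frame.duplicated(subset=COLUMNS[:4]).any()


# ---------------------------------------------------------------------------
# template IO


def _parse_value_cell(cell: object, row: int, col: str) -> float:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return math.nan
    text = str(cell).strip()
    if text.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise TemplateError(
            f"non-numeric value {text!r} in row {row}, column {col!r}"
        ) from None


def _resolve_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".tab", ".txt"}:
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix in {".xlsx", ".xls"}:
        return "spreadsheet"
    raise TemplateError(f"cannot infer template dialect from {path.name!r}")


def read_template(
    path: str | Path,
    dialect: Literal["tsv", "csv", "spreadsheet"] | None = None,
) -> ExpressionDataset:
    """Read an expression template into an :class:`ExpressionDataset`.

    Leading ``#key: value`` lines populate :class:`ExperimentMetadata`;
    the header row may name the columns in any order.
    """
    path = Path(path)
    if not path.exists():
        raise TemplateError(f"template file not found: {path}")
    dialect = _resolve_dialect(path, dialect)

    meta = ExperimentMetadata()
    if dialect == "spreadsheet":
        raw = pd.read_excel(path, dtype=object)
    else:
        sep = "\t" if dialect == "tsv" else ","
        meta_lines: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    meta_lines.append(line[1:].rstrip("\n"))
                else:
                    break
        for line in meta_lines:
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key == "project_name":
                meta.project_name = val
            elif key == "subjects":
                meta.subjects = val
            elif key == "source_note":
                meta.source_note = val
        raw = pd.read_csv(
            path, sep=sep, comment="#", dtype=object, skip_blank_lines=True
        )

    raw.columns = [str(c).strip().lower() for c in raw.columns]
    absent = [c for c in MANDATORY if c not in raw.columns]
    if absent:
        raise TemplateError(
            f"template lacks mandatory column(s) {absent}; found {list(raw.columns)}"
        )
    frame = pd.DataFrame()
    frame["gene_id"] = raw["gene_id"].astype(str)
    frame["spatial_id"] = raw["spatial_id"].astype(str)
    frame["condition"] = (
        raw["condition"].fillna("default").astype(str) if "condition" in raw else "default"
    )
    frame["time"] = raw["time"].fillna("").astype(str) if "time" in raw else ""
    if "replicate" in raw:
        frame["replicate"] = (
            pd.to_numeric(raw["replicate"], errors="coerce").fillna(1).astype(int)
        )
    else:
        frame["replicate"] = 1
    frame["value"] = [
        _parse_value_cell(cell, i + 1, "value")
        for i, cell in enumerate(raw["value"].tolist())
    ]
    return ExpressionDataset(frame, meta)


def write_template(ds: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset back to canonical TSV; inverse of :func:`read_template`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        m = ds.metadata
        fh.write(f"#project_name: {m.project_name}\n")
        fh.write(f"#subjects: {m.subjects}\n")
        if m.source_note:
            fh.write(f"#source_note: {m.source_note}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for row in ds.frame.itertuples(index=False):
            value = "NA" if pd.isna(row.value) else repr(float(row.value))
            fh.write(
                f"{row.gene_id}\t{row.spatial_id}\t{row.condition}\t"
                f"{row.time}\t{row.replicate}\t{value}\n"
            )
    return path


# ---------------------------------------------------------------------------
# transforms


def aggregate_replicates(
    ds: ExpressionDataset, stat: Literal["mean", "median"] = "mean"
) -> ExpressionDataset:
    """Collapse replicates to one value per (gene, spatial, condition, time).

    Missing replicates are ignored; a group whose replicates are all
    missing stays missing.  Idempotent.
    """
    if stat not in {"mean", "median"}:
        raise TemplateError(f"unknown aggregation stat {stat!r}")
    grouped = (
        ds.frame.groupby(COLUMNS[:4], sort=True, dropna=False)["value"]
        .agg(stat)  # pandas skips NaN; all-NaN groups yield NaN
        .reset_index()
    )
    grouped["replicate"] = 1
    return ExpressionDataset(grouped[COLUMNS], ds.metadata)


def derive_difference(
    ds: ExpressionDataset, cond_a: str, cond_b: str
) -> ExpressionDataset:
    """Per-segment difference ``value(cond_a) - value(cond_b)``.

    The result carries the condition label ``"a-b"``.  Pairs missing on
    either side are missing in the result.  Antisymmetric in (a, b).
    """
    available = ds.conditions()
    for cond in (cond_a, cond_b):
        if cond not in available:
            raise TemplateError(
                f"unknown condition {cond!r}; available: {available}"
            )
    if not ds.is_aggregated():
        ds = aggregate_replicates(ds)
    keys = ["gene_id", "spatial_id", "time"]
    a = ds.frame[ds.frame["condition"] == cond_a][keys + ["value"]]
    b = ds.frame[ds.frame["condition"] == cond_b][keys + ["value"]]
    merged = a.merge(b, on=keys, how="outer", suffixes=("_a", "_b"))
    merged["value"] = merged["value_a"] - merged["value_b"]
    merged["condition"] = f"{cond_a}-{cond_b}"
    merged["replicate"] = 1
    meta = ExperimentMetadata(
        project_name=ds.metadata.project_name,
        subjects=ds.metadata.subjects,
        source_note=f"difference {cond_a} - {cond_b}",
    )
    return ExpressionDataset(merged[COLUMNS], meta)
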