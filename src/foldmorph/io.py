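"""Reading, validating and writing per-hemisphere morphometric tables.

The expected table is one row per hemisphere with columns

    subject_id, hemisphere, group, age, sex, At_mm2, Ae_mm2, T_mm, side_of_onset

where At_mm2 is the total pial surface area, Ae_mm2 the exposed (smooth
envelope) surface area and T_mm the mean cortical thickness, all in the
units FreeSurfer produces (mm^2, mm).  Only subject_id, hemisphere and the
three morphometrics are required.  A YAML column mapping lets users rename
their own headers onto this schema.  Unknown columns pass through
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "SubjectTable",
    "read_subject_table",
    "write_table",
    "select_hemisphere_records",
]

REQUIRED_COLUMNS = ("subject_id", "hemisphere", "At_mm2", "Ae_mm2", "T_mm")
OPTIONAL_COLUMNS = ("group", "age", "sex", "side_of_onset")
MORPHO_COLUMNS = ("At_mm2", "Ae_mm2", "T_mm")

_DIALECT_SEP = {"csv": ",", "tsv": "\t"}


@dataclass
class SubjectTable:
    """An ordered collection of per-hemisphere records with provenance.

    Attributes
    ----------
    data
        The validated rows, one hemisphere each.
    provenance
        Human-readable log of where the table came from and what was done
        to it (corrections applied, rows rejected, recodings).
    rejected
        Rows that failed validation, with a ``reason`` column.
    """

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    rejected: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SubjectTable":
        rej = None if self.rejected is None else self.rejected.copy()
        return SubjectTable(self.data.copy(), list(self.provenance), rej)


def _resolve_column_map(column_map) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    if not isinstance(column_map, dict):
        raise ConfigurationError("column map must be a mapping of source -> schema name")
    return column_map


def read_subject_table(path, dialect: str = "csv", column_map=None) -> SubjectTable:
    """Read and validate a per-hemisphere morphometric table.

    Rows with non-positive At/Ae/T are rejected (kept in ``.rejected``
    with a reason); a non-numeric morphometric cell raises
    :class:`~foldmorph.errors.ParseError` naming the row; a missing
    required column raises :class:`~foldmorph.errors.SchemaError`.  A
    gyrification index below 1 (At < Ae) is physically unusual but
    representable, so it only triggers a warning.
    """
    if dialect not in _DIALECT_SEP:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    path = Path(path)
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype={"subject_id": str})
    df = df.rename(columns=_resolve_column_map(column_map))

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    provenance = [f"read {len(df)} rows from {path} ({dialect})"]

    for col in MORPHO_COLUMNS + (("age",) if "age" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ParseError(f"non-numeric value in column {col!r} at row(s) {rows}")
        df[col] = coerced

    # positivity: reject offending rows, keep a per-row report
    reasons = pd.Series("", index=df.index)
    for col in MORPHO_COLUMNS:
        bad = ~(df[col] > 0)
        reasons[bad] += f"{col} must be > 0; "
    bad_mask = reasons != ""
    rejected = None
    if bad_mask.any():
        rejected = df[bad_mask].copy()
        rejected["reason"] = reasons[bad_mask].str.rstrip("; ")
        df = df[~bad_mask].copy()
        provenance.append(
            f"rejected {len(rejected)} row(s) failing positivity: "
            + "; ".join(f"row {i}: {r}" for i, r in rejected["reason"].items())
        )

    dup = df.duplicated(subset=["subject_id", "hemisphere"])
    if dup.any():
        raise ParseError(
            "duplicate (subject_id, hemisphere) pairs at row(s) "
            + ", ".join(str(i) for i in df.index[dup][:10])
        )

    low_gi = df["At_mm2"] < df["Ae_mm2"]
    if low_gi.any():
        warnings.warn(
            f"{int(low_gi.sum())} row(s) have At < Ae (gyrification index < 1)",
            stacklevel=2,
        )

    if "sex" in df.columns and df["sex"].notna().any():
        levels = sorted(df["sex"].dropna().astype(str).unique())
        if not set(levels) <= {"0", "1"}:
            if len(levels) > 2:
                raise ParseError(f"sex must be binary; found levels {levels}")
            mapping = {lvl: float(i) for i, lvl in enumerate(levels)}
            df["sex"] = df["sex"].astype(str).map(mapping)
            provenance.append(f"sex recoded: {mapping}")
        else:
            df["sex"] = pd.to_numeric(df["sex"])

    return SubjectTable(df.reset_index(drop=True), provenance, rejected)


def write_table(table, path, dialect: str = "csv") -> None:
    """Write a table so that reading it back reproduces every numeric field.

    Floats are written with their shortest round-tripping representation
    (pandas' default ``str``), so the write -> read cycle is lossless.
    """
    if dialect not in _DIALECT_SEP:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = getattr(table, "data", table)
    df.to_csv(path, sep=_DIALECT_SEP[dialect], index=False)


def select_hemisphere_records(table: SubjectTable, mode: str = "all") -> SubjectTable:
    """Filter rows by hemisphere.

    Modes: ``all`` (no filter), ``left``, ``right``, and ``ipsilateral``
    which keeps, for rows labelled with a ``side_of_onset``, only the
    hemisphere on that side.  Rows without a side label (typically the
    reference cohort, whose lateralization relative to patients is a study
    design choice) are kept whole; subset them beforehand if a matched
    design is wanted.
    """
    if mode == "all":
        return table.copy()
    df = table.data
    if mode in ("left", "right"):
        out = df[df["hemisphere"] == mode]
        note = f"selected {mode} hemispheres: {len(out)}/{len(df)} rows"
    elif mode == "ipsilateral":
        if "side_of_onset" not in df.columns:
            raise ConfigurationError(
                "ipsilateral selection requires a side_of_onset column"
            )
        side = df["side_of_onset"].astype("object")
        labelled = side.isin(["left", "right"])
        keep = ~labelled | (df["hemisphere"] == side)
        out = df[keep]
        note = (
            f"ipsilateral selection: kept {len(out)}/{len(df)} rows "
            f"({int(labelled.sum())} lateralized)"
        )
    else:
        raise ConfigurationError(f"unknown hemisphere mode {mode!r}")
    new = SubjectTable(out.reset_index(drop=True), list(table.provenance), table.rejected)
    new.provenance.append(note)
    return new
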