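"""CSV input/output and input validation.

The canonical input is one row per competition replicate:

    abr_allele, ko_allele, antibiotic, temperature, replicate, orientation,
    d_comp_initial, d_ref_initial, d_comp_final, d_ref_final

UTF-8, header required, '.' decimal point.  All pipeline artifacts are plain
CSV with fixed column orders and full float precision so runs diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DENSITY_COLS,
    KEY_COLS,
    ORIENTATIONS,
    RECORD_COLS,
    REPLICATE_KEY,
    SchemaError,
)


def read_records(path) -> pd.DataFrame:
    """Read a competition-record CSV, enforcing the schema."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df[RECORD_COLS]


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class ValidationReport:
    """Outcome of validating an input table: hard errors, grid gaps, warnings."""

    n_records: int = 0
    schema_errors: list[str] = field(default_factory=list)
    grid_errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.schema_errors and not self.grid_errors

    def summary(self) -> str:
        lines = [f"records: {self.n_records}"]
        for label, items in (
            ("error", self.schema_errors),
            ("grid-error", self.grid_errors),
            ("warning", self.warnings),
        ):
            lines += [f"{label}: {msg}" for msg in items]
        if self.ok and not self.warnings:
            lines.append("validation passed with zero errors")
        return "\n".join(lines)


def validate_frame(df: pd.DataFrame) -> ValidationReport:
    """Validate schema, types, positivity, duplicates, and grid completeness."""
    rep = ValidationReport(n_records=len(df))
    missing = [c for c in RECORD_COLS if c not in df.columns]
    if missing:
        rep.schema_errors.append(f"missing column(s): {missing}")
        return rep
    if len(df) == 0:
        rep.schema_errors.append("no data rows")
        return rep
    for col in ["antibiotic", "temperature", "replicate"] + DENSITY_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            rows = list(df.index[bad][:5])
            rep.schema_errors.append(f"non-numeric {col!r} in row(s) {rows}")
    for col in DENSITY_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~(vals > 0)
        if bad.any():
            rows = list(df.index[bad][:5])
            rep.schema_errors.append(
                f"non-positive density {col!r} in row(s) {rows}"
            )
    unknown = set(df["orientation"]) - set(ORIENTATIONS)
    if unknown:
        rep.schema_errors.append(
            f"unknown orientation label(s) {sorted(unknown)}; expected {ORIENTATIONS}"
        )
    dup = df.duplicated(subset=REPLICATE_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, REPLICATE_KEY].drop_duplicates().values.tolist()
        rep.schema_errors.append(f"duplicated replicate key(s): {keys[:5]}")
    if rep.schema_errors:
        return rep

    # grid completeness: every genotype at every environment
    cells = df[KEY_COLS].drop_duplicates()
    abr = sorted(cells["abr_allele"].unique())
    ko = sorted(cells["ko_allele"].unique())
    envs = cells[["antibiotic", "temperature"]].drop_duplicates()
    have = set(map(tuple, cells.values))
    for a in abr:
        for k in ko:
            for ab, t in envs.values:
                if (a, k, ab, t) not in have:
                    rep.grid_errors.append(
                        f"missing cell: genotype ({a}, {k}) at {ab} ug/ml, {t} C"
                    )
    n_per_cell = df.groupby(KEY_COLS).size()
    single = n_per_cell[n_per_cell == 1]
    if len(single):
        rep.warnings.append(
            f"{len(single)} cell(s) have a single replicate (SE undefined, "
            "will be imputed for bootstrap inference)"
        )
    return rep


def validate_input(path) -> ValidationReport:
    """Validate a competition-record CSV file."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    return validate_frame(df)
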