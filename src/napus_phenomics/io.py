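"""Tabular readers/writers with schema validation.

Every pipeline stage exchanges plain CSV (comma separated, UTF-8, '.'
decimal, one header row, empty string for missing) so any stage can be run
standalone from files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger("napus_phenomics")


class SchemaError(ValueError):
    """Header does not match the expected schema."""


class TableValidationError(ValueError):
    """A row violates a column constraint."""


@dataclass(frozen=True)
class Column:
    name: str
    dtype: str = "float"        # float | int | str | bool
    minimum: float | None = None
    allow_missing: bool = True


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]
    extra_numeric: bool = False      # unlisted columns validated as floats
    extra_minimum: float | None = None

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _coerce(series: pd.Series, col: Column, path: Path) -> pd.Series:
    if col.dtype == "str":
        return series.astype("string")
    if col.dtype == "bool":
        out = series.astype("string").str.strip().str.lower().map(_BOOL_MAP)
        bad = series.notna() & out.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise TableValidationError(
                f"{path}: column '{col.name}' line {row}: "
                f"cannot parse '{series[bad.idxmax()]}' as boolean"
            )
        return out.astype("boolean")
    numeric = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & numeric.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise TableValidationError(
            f"{path}: column '{col.name}' line {row}: "
            f"cannot parse '{series[bad.idxmax()]}' as {col.dtype}"
        )
    if col.minimum is not None:
        low = numeric < col.minimum
        if low.any():
            row = int(low.idxmax()) + 2
            raise TableValidationError(
                f"{path}: column '{col.name}' line {row}: value "
                f"{numeric[low.idxmax()]} below minimum {col.minimum}"
            )
    if col.dtype == "int":
        return numeric.astype("Int64")
    return numeric.astype(float)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against `schema`.

    Raises SchemaError if a declared column is absent and
    TableValidationError (with the 1-based file line) on bad values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True,
                     na_values=[""], encoding="utf-8")
    missing = [c for c in schema.column_names() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} required by schema "
            f"'{schema.name}'"
        )
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        series = _coerce(df[col.name], col, path)
        if not col.allow_missing and series.isna().any():
            row = int(series.isna().idxmax()) + 2
            raise TableValidationError(
                f"{path}: column '{col.name}' line {row}: missing value"
            )
        out[col.name] = series
    if schema.extra_numeric:
        declared = set(schema.column_names())
        for name in df.columns:
            if name in declared:
                continue
            out[name] = _coerce(
                df[name],
                Column(name, "float", minimum=schema.extra_minimum),
                path,
            )
    else:
        for name in df.columns:
            if name not in out.columns:
                out[name] = df[name].astype("string")
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a stage output as canonical CSV (UTF-8, '' for missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", na_rep="")
    return path


def log_filter(stage: str, rule: str, n_before: int, n_removed: int) -> None:
    """Record a filtering step: how many rows/cells a rule removed."""
    frac = n_removed / n_before if n_before else 0.0
    log.info("%s: rule '%s' removed %d of %d (%.1f%%)",
             stage, rule, n_removed, n_before, 100 * frac)


# ---------------------------------------------------------------------------
# Stage schemas
# ---------------------------------------------------------------------------

ROOT_SCHEMA = TableSchema(
    name="root_records",
    columns=(
        Column("plant_id", "str", allow_missing=False),
        Column("genotype_id", "str"),
        Column("habit", "str"),
        Column("run", "int", minimum=1),
        Column("frame", "int", minimum=1),
        Column("column", "int", minimum=1),
        Column("tray", "int", minimum=1),
        Column("pouch", "int", minimum=1),
        Column("paper_side", "str"),
        Column("seed_diameter", "float", minimum=0),
        Column("prl", "float", minimum=0),
        Column("lrl", "float", minimum=0),
        Column("lrn", "int", minimum=0),
        Column("germinated", "bool"),
        Column("emerged", "bool"),
        Column("deformed", "bool"),
    ),
)

POT_SCHEMA = TableSchema(
    name="pots",
    columns=(
        Column("pot_id", "str", allow_missing=False),
        Column("genotype_id", "str"),
        Column("habit", "str"),
        Column("role", "str"),
        Column("polytunnel", "str"),
        Column("replicate", "int", minimum=1),
        Column("sub_block", "int", minimum=1),
    ),
)

ICPMS_META_COLUMNS = (
    Column("run_id", "str", allow_missing=False),
    Column("position", "int", minimum=1),
    Column("role", "str", allow_missing=False),
    Column("tissue", "str"),
    Column("genotype_id", "str"),
    Column("pot_id", "str"),
    Column("dry_mass_g", "float", minimum=0),
    Column("digest_volume_l", "float", minimum=0),
    Column("dilution", "float", minimum=1),
)

ICPMS_SCHEMA = TableSchema(
    name="icpms_runs",
    columns=ICPMS_META_COLUMNS,
    extra_numeric=True,
    extra_minimum=0.0,  # raw readings are non-negative solution concentrations
)

GENOTYPE_SCHEMA = TableSchema(
    name="genotypes",
    columns=(
        Column("genotype_id", "str", allow_missing=False),
        Column("habit", "str", allow_missing=False),
        Column("role", "str", allow_missing=False),
        Column("tsw", "float", minimum=0),
    ),
)

TRAIT_MATRIX_SCHEMA = TableSchema(
    name="trait_matrix",
    columns=(Column("genotype_id", "str", allow_missing=False),
             Column("habit", "str")),
    extra_numeric=True,
)


def icpms_element_columns(df: pd.DataFrame) -> list[str]:
    meta = {c.name for c in ICPMS_META_COLUMNS}
    return [c for c in df.columns if c not in meta]
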