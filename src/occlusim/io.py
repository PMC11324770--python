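"""Table and configuration I/O with schema validation.

CSV schemas are declared as column -> dtype-kind maps; unknown columns are
preserved, violations are reported with row numbers.  The run configuration
round-trips through YAML unchanged and every pipeline run writes the
resolved config and package version next to its outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "load_table",
    "write_table",
    "RunConfig",
    "load_config",
    "save_config",
]


class SchemaError(ValueError):
    pass


#: required columns and kinds ("f" float, "i" integer, "s" string, "b" bool)
SCHEMAS: dict[str, dict[str, str]] = {
    "manifest": {"plate": "s", "well": "s", "field": "i", "compound": "s",
                 "concentration_um": "f", "role": "s", "path_nuc": "s",
                 "path_mask": "s", "path_junc": "s"},
    "field_metrics": {"plate": "s", "well": "s", "field": "i",
                      "nuclei_count": "i", "membrane_area_um2": "f",
                      "junction_at_membrane_area_um2": "f"},
    "well_metrics": {"plate": "s", "well": "s", "compound": "s",
                     "concentration_um": "f", "role": "s", "n_fields": "i",
                     "mean_nuclei_count": "f",
                     "membrane_area_per_cell_um2": "f",
                     "junction_area_per_cell_um2": "f"},
    "truth": {"compound": "s", "respiratory_risk": "b"},
    "fits": {"compound": "s", "ic50_um": "f", "established": "b",
             "classification": "s", "method": "s"},
    "profiles": {"time_h": "f", "generation": "i", "compartment": "s",
                 "concentration_um": "f"},
}

_BOOL_MAP = {"true": True, "false": False, "yes": True, "no": False,
             "1": True, "0": False}


def _coerce(series: pd.Series, kind: str, col: str) -> pd.Series:
    bad_rows: list[int] = []
    if kind == "s":
        return series.astype(str)
    if kind == "b":
        def to_bool(v):
            if isinstance(v, bool):
                return v
            s = str(v).strip().lower()
            return _BOOL_MAP.get(s)
        out = series.map(to_bool)
        bad_rows = list(series.index[out.isna()])
        if bad_rows:
            raise SchemaError(
                f"column {col!r}: unparseable boolean at rows {bad_rows}")
        return out.astype(bool)
    numeric = pd.to_numeric(series, errors="coerce")
    bad_rows = [int(i) for i in series.index[
        numeric.isna() & series.notna()]]
    if bad_rows:
        raise SchemaError(
            f"column {col!r}: non-numeric values at rows {bad_rows}")
    if kind == "i":
        frac = numeric.dropna() % 1
        bad_rows = [int(i) for i in frac.index[frac != 0]]
        if bad_rows:
            raise SchemaError(
                f"column {col!r}: non-integer values at rows {bad_rows}")
        return numeric.astype("Int64")
    return numeric.astype(float)


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Load and validate a CSV against a named schema.  Unknown columns are
    kept as-is; missing required columns or wrong-typed cells raise
    :class:`SchemaError` with row numbers."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    try:
        tbl = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    spec = SCHEMAS[schema]
    missing = set(spec) - set(tbl.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns "
                          f"{sorted(missing)} for schema {schema!r}")
    for col, kind in spec.items():
        tbl[col] = _coerce(tbl[col], kind, col)
    return tbl


def write_table(table: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Validate against the schema, then write CSV."""
    spec = SCHEMAS.get(schema)
    if spec is None:
        raise ValueError(f"unknown schema {schema!r}")
    missing = set(spec) - set(table.columns)
    if missing:
        raise SchemaError(f"table missing columns {sorted(missing)} "
                          f"for schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of an end-to-end run.  Nested dicts hold the
    per-stage options; everything round-trips through YAML unchanged."""

    out_dir: str = "occlusim_run"
    master_seed: int = 0
    log_level: str = "INFO"
    generator: dict = dataclasses.field(default_factory=dict)
    quantify: dict = dataclasses.field(default_factory=dict)
    doseresponse: dict = dataclasses.field(default_factory=dict)
    pbpk: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
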