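"""Delimited-table I/O with schema validation and provenance headers.

Dialect: comma-separated, '.' decimal, UTF-8, '#' comment lines.  Every file
written here starts with provenance comment lines (package version, seed,
config hash) so a pipeline's outputs are self-describing.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

SCHEMAS: dict[str, dict] = {
    "traces": {
        "columns": ["replicate", "conc_M", "time_s", "signal"],
        "numeric": ["conc_M", "time_s", "signal"],
    },
    "fits": {
        "columns": ["replicate", "conc_M", "phase", "amplitude", "k_obs", "offset"],
        "numeric": ["conc_M", "amplitude", "k_obs", "offset"],
    },
    "plate": {
        "columns": ["well", "time_min", "channel", "role", "intensity"],
        "numeric": ["time_min", "intensity"],
        "categories": {"channel": {"400", "480"}, "role": {"sample", "red", "ox"}},
    },
    "a340": {
        "columns": ["time_s", "a340"],
        "numeric": ["time_s", "a340"],
    },
    "census": {
        "columns": ["composition", "count"],
        "numeric": ["count"],
    },
    "oxd": {
        "columns": ["well", "time_min", "oxd", "oxd_raw"],
        "numeric": ["time_min", "oxd", "oxd_raw"],
    },
}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    for col in spec["columns"]:
        if col not in df.columns:
            raise SchemaError(f"table missing required column {col!r} for schema {schema!r}")
    if len(df) < 1:
        raise SchemaError("table has no data rows")
    for col in spec.get("numeric", []):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"column {col!r} has unparseable numeric value "
                f"{df[col][bad].iloc[0]!r} near line {row}"
            )
        df[col] = converted
    for col, allowed in spec.get("categories", {}).items():
        vals = set(df[col].astype(str))
        if not vals <= allowed:
            raise SchemaError(
                f"column {col!r} contains invalid categories {sorted(vals - allowed)}; "
                f"allowed: {sorted(allowed)}"
            )
    return df


def load_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV (skipping '#' provenance lines) and validate its schema."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#", dtype=str)
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: str, metadata: dict | None = None) -> None:
    """Validate, prepend provenance comment lines, and write CSV."""
    from . import __version__

    validate_table(df.copy(), schema)
    meta = {"prxkit_version": __version__, "schema": schema}
    if metadata:
        meta.update(metadata)
    meta.setdefault("config_hash", config_hash(meta))
    buf = io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())
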