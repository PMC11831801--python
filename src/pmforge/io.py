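"""Readers/writers for the table schemas, config files and run manifests.

All tables are long/tidy CSV, UTF-8, '.' decimal, no thousands
separators. Reading validates against the schema and the table
invariants: hard violations raise, unknown extra columns are accepted
with a warning (forward compatibility).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from pmforge.core_inventory import (
    ACTIVITY_COLUMNS,
    CONTROL_COLUMNS,
    EF_COLUMNS,
    SPLIT_COLUMNS,
    Tables,
    emissions_to_tg,
    validate_tables,
)

logger = logging.getLogger(__name__)

TABLE_FILES = {
    "activities": "activities.csv",
    "splits": "splits.csv",
    "efs": "efs.csv",
    "controls": "controls.csv",
}

_SCHEMAS = {
    "activities": ACTIVITY_COLUMNS,
    "splits": SPLIT_COLUMNS,
    "efs": EF_COLUMNS,
    "controls": CONTROL_COLUMNS,
}

_NUMERIC = {
    "activities": ("amount",),
    "splits": ("share",),
    "efs": ("ef_tsp", "f_fine", "f_mid", "f_coarse", "bc_frac", "oc_frac", "cv"),
    "controls": ("penetration", "eta_fine", "eta_mid", "eta_coarse"),
}


def _read_one(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{name} table file not found: {path}")
    df = pd.read_csv(path)
    cols = _SCHEMAS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} in {name} table")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df[list(cols)]
    for col in _NUMERIC[name]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    if "year" in cols:
        df["year"] = pd.to_numeric(df["year"], downcast="integer")
    return df


def read_tables(directory: str | Path, validate: bool = True) -> Tables:
    """Read the four inventory tables from a directory of CSV files.

    Fails fast on missing files/columns, unparseable numerics, or (with
    ``validate=True``) any table-invariant violation.
    """
    directory = Path(directory)
    frames = {name: _read_one(directory / fname, name) for name, fname in TABLE_FILES.items()}
    tables = Tables(**frames)
    if validate:
        violations = validate_tables(*tables)
        if violations:
            head = "; ".join(str(v) for v in violations[:5])
            raise ValueError(f"{len(violations)} table invariant violation(s): {head}")
    return tables


def write_tables(tables: Tables, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        getattr(tables, name).to_csv(path, index=False)
        out[name] = path
    return out


def write_emissions(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an emission table as long CSV in Tg."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    emissions_to_tg(table).to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_config(path: str | Path) -> dict:
    """Parse a YAML/JSON scenario or pipeline config into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per pipeline run."""

    command: str
    inputs: dict[str, str]  # path -> sha256
    config: dict
    seed: int
    version: str
    started: str
    finished: str


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    return write_json(asdict(manifest), path)


def utc_now() -> str:
    return datetime.now(timezone.utc).isoformat()


def hash_inputs(paths: Mapping[str, Path] | list[Path]) -> dict[str, str]:
    if isinstance(paths, Mapping):
        paths = list(paths.values())
    return {str(p): sha256_file(p) for p in paths}
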