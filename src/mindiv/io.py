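"""Configuration loading and table round-tripping.

All tables are plain CSV with a versioned comment header; configuration
files are YAML or JSON mirroring the :class:`~mindiv.params.SimConfig`
field names exactly, with unknown keys rejected.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .params import SimConfig
from .state import EVENT_COLUMNS, TRACKING_COLUMNS

TABLE_HEADER = "# mindiv table v1"


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


def load_config(path: Union[str, Path]) -> SimConfig:
    """Read and validate a run configuration file (YAML or JSON).

    An empty file yields all defaults; unknown keys and invalid values
    raise :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SimConfig()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        return SimConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return SimConfig(**data)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration field(s): {fields}") from exc


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a table as CSV with the versioned header, 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(TABLE_HEADER + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_table(
    path: Union[str, Path], required: Optional[List[str]] = None
) -> pd.DataFrame:
    """Read a CSV table, tolerating the versioned comment header.

    ``required`` columns missing from the file raise a named error;
    malformed rows raise with the line number (pandas' parser message).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def read_tracking(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, required=[c for c in TRACKING_COLUMNS if c != "n_clusters"])


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, required=EVENT_COLUMNS)


def write_summary(summary: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
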