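"""File formats and run configuration shared by the command-line pipeline.

Counts travel as JSON (``{"e2n": {"expert": ..., "peer": ...}, "p2p":
...}``, with an extra first/last nesting for eight-cell tables) or as
long-format CSV; participant cohorts as CSV; grids as long-format CSV;
summaries and reports as JSON.  A YAML or JSON config document can supply
any subcommand option, with explicit command-line flags taking precedence.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .simulator import CountTable

__all__ = ["read_counts", "write_counts", "load_config", "write_json"]


def read_counts(path: str | Path) -> CountTable:
    """Load a count table from ``.json`` or ``.csv`` (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return CountTable.from_json(path)
    if path.suffix.lower() == ".csv":
        return CountTable.from_csv(path)
    raise ValueError(f"unsupported counts format {path.suffix!r} (use .json or .csv)")


def write_counts(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        table.to_json(path)
    elif path.suffix.lower() == ".csv":
        table.to_csv(path)
    else:
        raise ValueError(f"unsupported counts format {path.suffix!r} (use .json or .csv)")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config document into a flat option mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config document must be a mapping of option names to values")
    return data


def write_json(document: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(document, indent=2, sort_keys=True) + "\n")
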