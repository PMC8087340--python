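"""Loaders for shipped and user-supplied configuration files.

Three kinds of config are shipped as package data:

* ``score_table_default_v1.yaml`` — the 51-item food roster, its 20
  groups and the per-class penalty points ("default_v1");
* ``params_default_v1.yaml`` — scoring constants ("default_v1");
* ``profile_pilot2019.yaml`` — the simulator profile calibrated to the
  pilot cohort ("pilot2019").

Each ``load_raw_*`` function accepts a shipped short name or a
filesystem path to a YAML/JSON file with the same schema.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

_DATA = resources.files("wakamola") / "data"


def _load(source: str | Path, shipped_name: str | None, shipped_file: str) -> dict:
    if shipped_name is not None and str(source) == shipped_name:
        text = (_DATA / shipped_file).read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_raw_score_table(source: str | Path = "default_v1") -> dict[str, Any]:
    return _load(source, "default_v1", "score_table_default_v1.yaml")


def load_raw_params(source: str | Path = "default_v1") -> dict[str, Any]:
    return _load(source, "default_v1", "params_default_v1.yaml")


def load_raw_profile(source: str | Path = "pilot2019") -> dict[str, Any]:
    return _load(source, "pilot2019", "profile_pilot2019.yaml")


@lru_cache(maxsize=1)
def default_item_ids() -> set[str]:
    """The canonical 51 food-item ids of the shipped score table."""
    return set(load_raw_score_table()["items"])


@lru_cache(maxsize=1)
def default_group_labels() -> dict[str, str]:
    """Food-group id -> human-readable label from the shipped table."""
    raw = load_raw_score_table()
    return {gid: g["label"] for gid, g in raw["groups"].items()}


@lru_cache(maxsize=1)
def items_by_group() -> dict[str, list[str]]:
    raw = load_raw_score_table()
    out: dict[str, list[str]] = {g: [] for g in raw["groups"]}
    for item, group in raw["items"].items():
        out[group].append(item)
    return out


def config_hash(obj: Any) -> str:
    """Short stable hash of a config mapping, for output provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
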