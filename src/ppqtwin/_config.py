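"""Loading of packaged YAML configuration (physiology coefficients, compound
file, tissue composition, trial designs)."""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load a YAML mapping from an arbitrary filesystem path."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at top level of {path}")
    return data


@functools.lru_cache(maxsize=None)
def load_packaged(name: str) -> dict[str, Any]:
    """Load one of the YAML files shipped under ppqtwin/data."""
    ref = resources.files("ppqtwin").joinpath("data", name)
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at top level of packaged {name}")
    return data


def physiology_coefficients() -> dict[str, Any]:
    return load_packaged("physiology_coefficients.yaml")


def tissue_composition() -> dict[str, Any]:
    return load_packaged("tissue_composition.yaml")


def compound_defaults() -> dict[str, Any]:
    return load_packaged("piperaquine_phosphate.yaml")


def trial_designs() -> dict[str, Any]:
    return load_packaged("trial_designs.yaml")
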