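"""Shipped protocol presets and flat config-file loading.

Presets are YAML files mapping field names of
:class:`~touchtask.core.ProtocolConfig` (plus a ``protocol`` key naming
the task structure). Users point the CLI at their own file of the same
shape.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .core import ProtocolConfig

PRESET_NAMES = ("phase1_shaping", "phase2_2afc", "phase3_reaching")


def _parse(doc: dict, origin: str) -> tuple[str, ProtocolConfig]:
    if not isinstance(doc, dict):
        raise ValueError(f"{origin}: config file must be a flat mapping")
    doc = dict(doc)
    protocol = doc.pop("protocol", "single_target")
    unknown = set(doc) - set(ProtocolConfig.model_fields)
    if unknown:
        raise ValueError(f"{origin}: unknown config keys {sorted(unknown)}")
    return protocol, ProtocolConfig(**doc)


def load_config_file(path) -> tuple[str, ProtocolConfig]:
    """Load (protocol_name, config) from a flat YAML config file."""
    path = Path(path)
    return _parse(yaml.safe_load(path.read_text()), str(path))


def load_preset(name: str) -> tuple[str, ProtocolConfig]:
    """Load one of the shipped presets by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {list(PRESET_NAMES)}")
    text = resources.files("touchtask").joinpath(f"presets/{name}.yaml").read_text()
    return _parse(yaml.safe_load(text), f"preset:{name}")
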