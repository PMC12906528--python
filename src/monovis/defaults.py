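"""Packaged default constants and lens-design presets.

Physical defaults (vertex distance, model-eye focal length, corneal SA,
CSF calibration) and the stylised design presets live in ``presets.yaml``
next to this module so they can be inspected and overridden without
touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml


@lru_cache(maxsize=1)
def load_defaults() -> dict[str, Any]:
    """Load and cache the packaged defaults file."""
    text = resources.files("monovis").joinpath("presets.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def preset_names() -> tuple[str, ...]:
    return tuple(load_defaults()["presets"])
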