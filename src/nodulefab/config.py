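"""Packaged default configuration.

The default study conditions (design grid, HU class bands, calibration
anchors, visibility/defect exclusions, virtual-CT parameters) live in
``data/defaults.yaml`` so they can be inspected and overridden without
touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

__all__ = ["defaults"]


@lru_cache(maxsize=1)
def defaults() -> dict:
    """Parsed contents of the packaged ``defaults.yaml``."""
    with resources.files("nodulefab.data").joinpath("defaults.yaml").open("r") as fh:
        return yaml.safe_load(fh)
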