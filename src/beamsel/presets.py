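"""Clinical protocol presets: fractionation and dose-volume limits.

Five hypofractionated SABR protocols ship as YAML files (prescription,
fraction count and the principal published dose-volume constraints for
each site); they parameterise constraint checking only — the synthetic
phantom does not reproduce any site's anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .metrics import Constraint

PRESET_NAMES = ("prostate_a", "prostate_b", "lung", "liver", "breast")


@dataclass(frozen=True)
class ProtocolPreset:
    name: str
    prescription_gy: float
    fractions: int
    protocol: str
    constraints: tuple[Constraint, ...]


def load_preset(name: str) -> ProtocolPreset:
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {PRESET_NAMES}")
    text = (resources.files("beamsel") / "protocols"
            / f"{name}.yaml").read_text()
    data = yaml.safe_load(text)
    cons = tuple(Constraint(**c) for c in data.pop("constraints"))
    return ProtocolPreset(constraints=cons, **data)
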