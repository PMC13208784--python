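"""YAML run configuration with explicit physical units.

Quantities may be given as plain numbers (interpreted as SI) or as strings
with a unit suffix, e.g. ``length_a: "24 mm"``, ``pressure_P: "-20 kPa"``,
``thickness_t: "200 um"``.  Supported units: m, mm, um (or µm/μm), nm for
lengths; Pa, kPa, MPa for pressures; plain numbers elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import yaml

_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pa": 1.0,
    "kpa": 1e3,
    "mpa": 1e6,
}


def parse_quantity(value) -> float:
    """Convert ``"24 mm"`` / ``{"value": 24, "unit": "mm"}`` / ``0.024`` to SI."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict):
        unit = value.get("unit", "")
        return parse_quantity(f"{value['value']} {unit}")
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            return float(parts[0])
        if len(parts) == 2:
            num, unit = parts
            key = unit.strip().lower()
            if key not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit {unit!r}")
            return float(num) * _UNIT_FACTORS[key]
    raise ValueError(f"cannot parse quantity {value!r}")


_MEMBRANE_QUANTITY_KEYS = (
    "length_a",
    "width_b",
    "thickness_t",
    "youngs_E",
    "poisson_nu",
    "pressure_P",
)


def load_config(path: str | Path) -> dict:
    """Load a YAML config, converting membrane quantities to SI floats."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    mem = cfg.get("membrane", {})
    for key in _MEMBRANE_QUANTITY_KEYS:
        if key in mem:
            mem[key] = parse_quantity(mem[key])
    return cfg
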