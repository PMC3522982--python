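"""Energy quantities, unit conversion, and flag parsing for energies and times.

Spectroscopy mixes electronvolts, millielectronvolts, wavenumbers and joules
freely; every public function in this package that takes an energy accepts an
:class:`EnergyQuantity` so the unit travels with the number.  Conversion
factors are CODATA 2018.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "EnergyQuantity",
    "convert_energy",
    "parse_energy",
    "parse_time",
    "EV_TO_CM1",
    "EV_TO_J",
    "HBAR_EV_S",
    "KB_EV_PER_K",
    "KT_300K_EV",
    "COULOMB_EV_ANG",
    "AMU_KG",
    "HBAR_J_S",
]

# CODATA 2018
HBAR_EV_S = 6.582119569e-16      # reduced Planck constant, eV s
HBAR_J_S = 1.054571817e-34       # reduced Planck constant, J s
EV_TO_J = 1.602176634e-19        # 1 eV in joules (exact)
EV_TO_CM1 = 8065.543937          # 1 eV in wavenumbers
KB_EV_PER_K = 8.617333262e-5     # Boltzmann constant, eV/K
KT_300K_EV = KB_EV_PER_K * 300.0  # 25.852 meV
COULOMB_EV_ANG = 14.39964        # e^2/(4 pi eps0), eV Angstrom
AMU_KG = 1.66053906660e-27       # unified atomic mass unit, kg

# canonical unit -> factor converting that unit to eV
_TO_EV = {
    "eV": 1.0,
    "meV": 1e-3,
    "cm^-1": 1.0 / EV_TO_CM1,
    "J": 1.0 / EV_TO_J,
}

_UNIT_ALIASES = {
    "ev": "eV",
    "mev": "meV",
    "cm^-1": "cm^-1",
    "cm-1": "cm^-1",
    "cm1": "cm^-1",
    "1/cm": "cm^-1",
    "wavenumber": "cm^-1",
    "wavenumbers": "cm^-1",
    "j": "J",
    "joule": "J",
}


def _canonical_unit(unit: str) -> str:
    key = unit.strip().lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(
            f"unknown energy unit {unit!r}; expected one of eV, meV, cm^-1, J"
        )
    return _UNIT_ALIASES[key]


@dataclass(frozen=True)
class EnergyQuantity:
    """An energy value together with its unit (eV, meV, cm^-1 or J)."""

    value: float
    unit: str = "eV"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _canonical_unit(self.unit))
        if not math.isfinite(self.value):
            raise ValueError(f"energy value must be finite, got {self.value!r}")

    def to(self, unit: str) -> "EnergyQuantity":
        """Return the physically equivalent quantity in ``unit``."""
        target = _canonical_unit(unit)
        if target == self.unit:
            return EnergyQuantity(self.value, target)
        ev = self.value * _TO_EV[self.unit]
        return EnergyQuantity(ev / _TO_EV[target], target)

    @property
    def eV(self) -> float:
        return self.value * _TO_EV[self.unit]

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} {self.unit}"


def convert_energy(quantity: EnergyQuantity, target_unit: str) -> EnergyQuantity:
    """Convert ``quantity`` to ``target_unit`` (eV, meV, cm^-1 or J)."""
    return quantity.to(target_unit)


def as_energy(value: "EnergyQuantity | float", unit: str = "eV") -> EnergyQuantity:
    """Coerce a bare float (interpreted in ``unit``) or EnergyQuantity."""
    if isinstance(value, EnergyQuantity):
        return value
    return EnergyQuantity(float(value), unit)


_QUANTITY_RE = re.compile(r"^\s*([-+]?[0-9.]+(?:[eE][-+]?[0-9]+)?)\s*([^\s0-9]+.*?)\s*$")

_TIME_TO_S = {
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9, "ps": 1e-12, "fs": 1e-15,
}


def parse_energy(text: str) -> EnergyQuantity:
    """Parse a unit-suffixed energy flag such as ``"200meV"`` or ``"2600cm-1"``."""
    m = _QUANTITY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse energy {text!r}; write e.g. '200meV'")
    return EnergyQuantity(float(m.group(1)), m.group(2))


def parse_time(text: str) -> float:
    """Parse a unit-suffixed time flag such as ``"0.15ns"``; returns seconds."""
    m = _QUANTITY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse time {text!r}; write e.g. '0.15ns'")
    unit = m.group(2).strip()
    unit = {"µs": "us", "sec": "s"}.get(unit, unit)
    if unit not in _TIME_TO_S:
        raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(_TIME_TO_S)}")
    return float(m.group(1)) * _TIME_TO_S[unit]


def format_2sf(x: float) -> str:
    """Two-significant-figure display string used in human-readable output."""
    if x == 0:
        return "0.0"
    return f"{x:.2g}"
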