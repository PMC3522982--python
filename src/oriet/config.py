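"""Validated run configuration (YAML) shared by the CLI subcommands.

Energies and times in config files carry explicit units ("200meV",
"0.15ns") and are parsed through :mod:`oriet.units`; unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .discrimination import ReceptorDefinition
from .kinetics import KineticsScenario
from .rates import ReceptorParams
from .units import EnergyQuantity, parse_energy, parse_time


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReceptorParamsConfig(_StrictModel):
    """Tunnelling parameters with unit-suffixed energies."""

    vibrational_quantum: str = "200meV"
    huang_rhys: float = 0.1
    reorganization: str = "30meV"
    matrix_element: str = "1meV"
    temperature_energy: str = "27meV"
    da_gap: Optional[str] = None

    @field_validator(
        "vibrational_quantum", "reorganization", "matrix_element",
        "temperature_energy", "da_gap",
    )
    @classmethod
    def _parseable_energy(cls, v: Optional[str]) -> Optional[str]:
        if v is not None:
            parse_energy(v)
        return v

    def build(self) -> ReceptorParams:
        return ReceptorParams(
            vibrational_quantum=parse_energy(self.vibrational_quantum),
            huang_rhys=self.huang_rhys,
            reorganization=parse_energy(self.reorganization),
            matrix_element=parse_energy(self.matrix_element),
            temperature_energy=parse_energy(self.temperature_energy),
            da_gap=parse_energy(self.da_gap) if self.da_gap else None,
        )

    @classmethod
    def from_params(cls, p: ReceptorParams) -> "ReceptorParamsConfig":
        def fmt(e: EnergyQuantity) -> str:
            return f"{e.to('meV').value:g}meV"

        return cls(
            vibrational_quantum=fmt(p.vibrational_quantum),
            huang_rhys=p.huang_rhys,
            reorganization=fmt(p.reorganization),
            matrix_element=fmt(p.matrix_element),
            temperature_energy=fmt(p.temperature_energy),
            da_gap=fmt(p.da_gap) if p.da_gap is not None else None,
        )


class KineticsConfig(_StrictModel):
    """Race-model timescales with unit-suffixed times."""

    tunnel_time_right: str = "0.1542ns"
    tunnel_time_wrong: str = "87.35ns"
    window_time: str = "31.6us"
    replenish_time: str = "31.6us"
    integration_window: str = "1ms"

    @field_validator("*")
    @classmethod
    def _parseable_time(cls, v: str) -> str:
        parse_time(v)
        return v

    def build(self) -> KineticsScenario:
        return KineticsScenario(
            tunnel_time_right=parse_time(self.tunnel_time_right),
            tunnel_time_wrong=parse_time(self.tunnel_time_wrong),
            window_time=parse_time(self.window_time),
            replenish_time=parse_time(self.replenish_time),
            integration_window=parse_time(self.integration_window),
        )


class ReceptorDefConfig(_StrictModel):
    name: str
    tuned_cm1: float
    window_cm1: float = 25.0
    s_min: float = 0.01
    s_max: float = 0.3

    def build(self) -> ReceptorDefinition:
        return ReceptorDefinition(
            name=self.name,
            tuned_frequency=self.tuned_cm1,
            resolution_window=self.window_cm1,
            coupling_range=(self.s_min, self.s_max),
        )


class RunConfig(_StrictModel):
    """Top-level config: tunnelling parameters, kinetics, receptor panel, seed."""

    receptor_params: ReceptorParamsConfig = Field(default_factory=ReceptorParamsConfig)
    kinetics: Optional[KineticsConfig] = None
    receptors: list[ReceptorDefConfig] = Field(default_factory=list)
    spectra: list[str] = Field(default_factory=list)
    output: Optional[str] = None
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(exclude_none=True), fh, sort_keys=False)


def load_receptors(path: str | Path) -> list[ReceptorDefinition]:
    """Load a receptor panel from a YAML list of {name, tuned_cm1, ...} entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [ReceptorDefConfig.model_validate(entry).build() for entry in raw]
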