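"""Closed-form oscillator, electrostatic and charge-transport quantities.

These are the desk-scale estimates that frame the tunnelling model: the
thermal amplitude of a molecular stretch, the Boltzmann probability that a
high-frequency mode is already excited, the donor/acceptor level splitting
produced by a nearby charge, diffusive vs field-biased charge supply rates,
and the frequency scaling under isotopic substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

from .units import (
    AMU_KG,
    COULOMB_EV_ANG,
    EV_TO_J,
    HBAR_J_S,
    KT_300K_EV,
    EnergyQuantity,
    as_energy,
)

__all__ = [
    "OscillatorSpec",
    "ChargePairGeometry",
    "TransportSpec",
    "TransportRates",
    "IsotopeFactor",
    "thermal_occupation",
    "rms_displacement",
    "coulomb_splitting",
    "diffusive_rate",
    "biased_rate",
    "isotope_frequency_factor",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """A harmonic mode: quantum ħω, oscillating mass (amu) and thermal energy k_BT.

    The hydrogen-stretch convention M = 1 amu (the proton carries the motion)
    is the default reading of ``mass``; pass a reduced mass explicitly when
    both partners move appreciably.
    """

    quantum: EnergyQuantity
    mass: float  # amu
    temperature_energy: EnergyQuantity

    def __post_init__(self) -> None:
        if self.quantum.eV <= 0:
            raise ValueError("oscillator quantum must be positive")
        if self.mass <= 0:
            raise ValueError("oscillator mass must be positive")
        if self.temperature_energy.eV < 0:
            raise ValueError("temperature energy must be non-negative")


def thermal_occupation(
    quantum: EnergyQuantity | float, temperature_energy: EnergyQuantity | float
) -> float:
    """Probability exp(−ħω₀/k_BT) that a mode is thermally excited.

    For a 0.2 eV odorant quantum at body temperature (k_BT ≈ 0.027 eV) this
    is ~6e-4: the mode is in its ground state before the electron arrives.
    The zero-temperature limit returns 0 exactly.
    """
    homega = as_energy(quantum).eV
    kt = as_energy(temperature_energy).eV
    if homega <= 0:
        raise ValueError("vibrational quantum must be positive")
    if kt < 0:
        raise ValueError("temperature energy must be non-negative")
    if kt == 0.0:
        return 0.0
    return math.exp(-homega / kt)


def rms_displacement(spec: OscillatorSpec) -> float:
    """Root-mean-square thermal displacement of a harmonic mode, in Å.

    x̄² = (ħ / 2Mω) · coth(ħω / 2k_BT); the T→0 limit is the zero-point
    amplitude sqrt(ħ/2Mω), and the classical limit recovers equipartition
    k_BT/(Mω²).
    """
    homega_j = spec.quantum.to("J").value
    mass_kg = spec.mass * AMU_KG
    kt_j = spec.temperature_energy.to("J").value
    # hbar/(2 M omega) = hbar^2 / (2 M * hbar omega)
    x2_zero_point = HBAR_J_S**2 / (2.0 * mass_kg * homega_j)
    if kt_j == 0.0:
        coth = 1.0
    else:
        coth = 1.0 / math.tanh(homega_j / (2.0 * kt_j))
    return math.sqrt(x2_zero_point * coth) * 1e10


@dataclass(frozen=True)
class ChargePairGeometry:
    """A point charge placed asymmetrically relative to donor and acceptor.

    ``r_donor``/``r_acceptor`` are the charge–site distances in Å; ``charge``
    is in units of e.  A screened dielectric ``dielectric`` ≥ 1 divides the
    bare Coulomb energies.
    """

    r_donor: float
    r_acceptor: float
    dielectric: float = 1.0
    charge: float = 1.0

    def __post_init__(self) -> None:
        if self.r_donor <= 0 or self.r_acceptor <= 0:
            raise ValueError("charge-site distances must be positive")
        if self.dielectric < 1:
            raise ValueError("dielectric constant must be >= 1")


def coulomb_splitting(geometry: ChargePairGeometry) -> EnergyQuantity:
    """Donor/acceptor energy separation (e²/ε)(1/R_A − 1/R_D), in eV.

    Positive when the charge sits closer to the acceptor (R_A < R_D).  A
    proton 5 Å from the donor and 4 Å from the acceptor, screened by ε = 3,
    splits otherwise identical sites by 0.24 eV ≈ 1936 cm⁻¹ — the right order
    for tuning a receptor to a vibrational quantum.
    """
    g = geometry
    ev = COULOMB_EV_ANG * g.charge**2 / g.dielectric * (1.0 / g.r_acceptor - 1.0 / g.r_donor)
    return EnergyQuantity(ev, "eV")


@dataclass(frozen=True)
class TransportSpec:
    """Charge supply to the donor: diffusion over a distance, optionally biased.

    ``diffusion_coefficient`` in cm²/s (1e-4 is typical of liquids),
    ``distance`` in nm, ``bias_potential`` in volts, ``charge`` in units of e.
    """

    diffusion_coefficient: float  # cm^2/s
    distance: float               # nm
    bias_potential: float = 0.0   # V
    charge: float = 1.0           # e
    temperature_energy: EnergyQuantity = EnergyQuantity(KT_300K_EV, "eV")

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")

    @property
    def _d_over_l2(self) -> float:
        d_nm2 = self.diffusion_coefficient * 1e14  # cm^2/s -> nm^2/s
        return d_nm2 / self.distance**2


class TransportRates(NamedTuple):
    diffusive: float        # s^-1
    biased: float           # s^-1
    bias_dominates: bool    # qU > k_BT


def diffusive_rate(spec: TransportSpec) -> float:
    """Unbiased diffusion rate D/L² (s⁻¹)."""
    return spec._d_over_l2


def biased_rate(spec: TransportSpec) -> TransportRates:
    """Field-biased drift rate (qU/k_BT)·D/L² and whether it beats diffusion.

    The drift channel wins exactly when the bias energy qU exceeds k_BT.
    """
    diff = spec._d_over_l2
    qu_ev = spec.charge * spec.bias_potential  # e * V = eV
    kt = spec.temperature_energy.eV
    biased = (qu_ev / kt) * diff
    return TransportRates(diffusive=diff, biased=biased, bias_dominates=qu_ev > kt)


class IsotopeFactor(NamedTuple):
    ratio: float            # new frequency / old frequency
    fractional_drop: float  # 1 - ratio


def isotope_frequency_factor(
    model: Literal["proton_only", "reduced_mass"] = "proton_only",
    mass_original: float = 1.0,
    mass_substituted: float = 2.0,
    partner_mass: float | None = None,
) -> IsotopeFactor:
    """Frequency scaling ω_new/ω_old on isotopic substitution.

    ``proton_only``: only the light atom moves, ω ∝ 1/√m, so H→D gives
    ratio 1/√2 and a fractional drop 1 − 1/√2 ≈ 0.29 (about 800 cm⁻¹ for
    stretches near 2700 cm⁻¹).  ``reduced_mass``: both partners move and the
    ratio is sqrt(μ_old/μ_new) with μ = mM/(m+M); requires ``partner_mass``.
    """
    if mass_original <= 0 or mass_substituted <= 0:
        raise ValueError("masses must be positive")
    if model == "proton_only":
        ratio = math.sqrt(mass_original / mass_substituted)
    elif model == "reduced_mass":
        if partner_mass is None or partner_mass <= 0:
            raise ValueError("reduced_mass model requires a positive partner_mass")
        mu_old = mass_original * partner_mass / (mass_original + partner_mass)
        mu_new = mass_substituted * partner_mass / (mass_substituted + partner_mass)
        ratio = math.sqrt(mu_old / mu_new)
    else:
        raise ValueError(f"unknown isotope model {model!r}")
    return IsotopeFactor(ratio=ratio, fractional_drop=1.0 - ratio)
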