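"""Spectral discrimination layer: which odorant spectra activate which receptors.

A receptor tuned to a frequency δ detects a vibrational mode if the mode
falls within the receptor's spectral resolution window (default ±25 cm⁻¹ —
differences smaller than that are unlikely to be resolved) and the mode's
electron–vibration coupling S lies in the detectable range (default
0.01–0.3: weaker couplings fire too rarely, stronger ones open competing
multiphonon channels).  An odorant's "smell", at this level, is the row of
receptor activations it produces; two odorants smell different exactly when
their rows differ.  Isotope substitution lowers H-mode frequencies by 1/√2
(proton-only picture) and so can silently move a mode out of a receptor's
window — the model's cleanest testable prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .physics import IsotopeFactor, isotope_frequency_factor

__all__ = [
    "VibrationalMode",
    "OdorantSpectrum",
    "ReceptorDefinition",
    "ModeMatch",
    "ActivationReport",
    "BROAD_COUPLING_RANGE",
    "USEFUL_COUPLING_RANGE",
    "read_spectrum",
    "write_spectrum",
    "receptor_activation",
    "activation_matrix",
    "apply_isotope_substitution",
    "isotope_discrimination",
    "generate_synthetic_spectrum",
]

#: Detectable-coupling presets: the broad range, and the narrower range
#: typical of couplings actually computed for odorants.
BROAD_COUPLING_RANGE = (0.01, 0.3)
USEFUL_COUPLING_RANGE = (0.05, 0.3)


@dataclass(frozen=True)
class VibrationalMode:
    """One odorant normal mode: frequency (cm⁻¹), coupling S, optional reduced mass."""

    label: str
    frequency: float
    huang_rhys: float
    reduced_mass: float | None = None
    involves_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"mode {self.label!r}: frequency must be positive")
        if self.huang_rhys < 0:
            raise ValueError(f"mode {self.label!r}: Huang-Rhys factor must be non-negative")


@dataclass(frozen=True)
class OdorantSpectrum:
    """A named odorant with its table of vibrational modes."""

    name: str
    modes: tuple[VibrationalMode, ...] = ()
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("odorant name must be non-empty")
        object.__setattr__(self, "modes", tuple(self.modes))
        labels = [m.label for m in self.modes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate mode labels: {dupes}")


@dataclass(frozen=True)
class ReceptorDefinition:
    """A receptor tuned to ``tuned_frequency`` with a finite resolution window.

    ``resolution_window`` is the half-width in cm⁻¹ (inclusive at the
    boundary: a mode exactly at the edge counts as detected);
    ``coupling_range`` is the inclusive (S_min, S_max) acceptance band.
    """

    name: str
    tuned_frequency: float
    resolution_window: float = 25.0
    coupling_range: tuple[float, float] = BROAD_COUPLING_RANGE

    def __post_init__(self) -> None:
        if self.resolution_window <= 0:
            raise ValueError("resolution window must be positive")
        s_min, s_max = self.coupling_range
        if not (0 <= s_min < s_max):
            raise ValueError("coupling range must satisfy 0 <= S_min < S_max")


class ModeMatch(NamedTuple):
    label: str
    frequency: float
    huang_rhys: float
    detuning: float  # frequency - tuned_frequency, cm^-1


@dataclass(frozen=True)
class ActivationReport:
    """Decision for one (odorant, receptor) pair with the qualifying modes."""

    odorant: str
    receptor: str
    activated: bool
    matching_modes: tuple[ModeMatch, ...] = ()

    def __post_init__(self) -> None:
        if self.activated != bool(self.matching_modes):
            raise ValueError("activated flag must agree with matching_modes")


_REQUIRED_COLUMNS = ("label", "freq_cm1", "huang_rhys")
_OPTIONAL_COLUMNS = ("reduced_mass_amu", "has_H")


def read_spectrum(path: str | Path, name: str | None = None) -> OdorantSpectrum:
    """Read a tab-separated mode table into an :class:`OdorantSpectrum`.

    Required columns: ``label``, ``freq_cm1``, ``huang_rhys``; optional:
    ``reduced_mass_amu``, ``has_H``.  Malformed rows are reported with their
    line numbers.  A header-only file yields an empty spectrum with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: header only, no modes", stacklevel=2)
    modes = []
    errors = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            modes.append(
                VibrationalMode(
                    label=str(row["label"]),
                    frequency=float(row["freq_cm1"]),
                    huang_rhys=float(row["huang_rhys"]),
                    reduced_mass=(
                        float(row["reduced_mass_amu"])
                        if "reduced_mass_amu" in df.columns and pd.notna(row["reduced_mass_amu"])
                        else None
                    ),
                    involves_hydrogen=(
                        bool(int(row["has_H"]))
                        if "has_H" in df.columns and pd.notna(row["has_H"])
                        else False
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))
    return OdorantSpectrum(name=name or path.stem, modes=tuple(modes))


def write_spectrum(spectrum: OdorantSpectrum, path: str | Path) -> None:
    """Write a spectrum as the tab-separated mode table read by :func:`read_spectrum`."""
    rows = [
        {
            "label": m.label,
            "freq_cm1": m.frequency,
            "huang_rhys": m.huang_rhys,
            "reduced_mass_amu": m.reduced_mass,
            "has_H": int(m.involves_hydrogen),
        }
        for m in spectrum.modes
    ]
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS[:1]) + ["freq_cm1", "huang_rhys", "reduced_mass_amu", "has_H"])
    df.to_csv(path, sep="\t", index=False)


def receptor_activation(
    spectrum: OdorantSpectrum, receptor: ReceptorDefinition
) -> ActivationReport:
    """Decide whether ``spectrum`` activates ``receptor`` and list qualifying modes.

    A mode qualifies when |frequency − δ| ≤ window and S_min ≤ S ≤ S_max,
    boundaries inclusive.  The decision depends only on (frequency, S) pairs:
    mode order and labels are irrelevant, so mirror-image molecules (identical
    frequency/coupling multisets) always produce identical decisions.
    """
    s_min, s_max = receptor.coupling_range
    matches = tuple(
        ModeMatch(m.label, m.frequency, m.huang_rhys, m.frequency - receptor.tuned_frequency)
        for m in spectrum.modes
        if abs(m.frequency - receptor.tuned_frequency) <= receptor.resolution_window
        and s_min <= m.huang_rhys <= s_max
    )
    return ActivationReport(
        odorant=spectrum.name,
        receptor=receptor.name,
        activated=bool(matches),
        matching_modes=matches,
    )


def activation_matrix(
    odorants: Sequence[OdorantSpectrum], receptors: Sequence[ReceptorDefinition]
) -> pd.DataFrame:
    """Boolean activation matrix: one row per odorant, one column per receptor.

    Under combinatorial coding two odorants are distinguishable at the
    receptor level exactly when their rows differ.
    """
    if not odorants:
        raise ValueError("need at least one odorant spectrum")
    data = {
        r.name: [receptor_activation(o, r).activated for o in odorants]
        for r in receptors
    }
    return pd.DataFrame(data, index=[o.name for o in odorants], dtype=bool)


def apply_isotope_substitution(
    spectrum: OdorantSpectrum,
    rule: str | Iterable[str] = "all_H_to_D",
    model: str = "proton_only",
    mass_original: float = 1.0,
    mass_substituted: float = 2.0,
) -> OdorantSpectrum:
    """Return a new spectrum with hydrogen-mode frequencies isotopically shifted.

    ``rule`` is either ``"all_H_to_D"`` (shift every mode flagged
    ``involves_hydrogen``) or an iterable of mode labels.  Frequencies of
    affected modes are multiplied by the model's frequency ratio (1/√2 for
    proton-only H→D; per-mode reduced masses for the ``reduced_mass`` model);
    couplings and all other modes are untouched.  The input is not modified.
    Applying the rule twice shifts twice — deuteration is not idempotent.
    """
    if isinstance(rule, str):
        if rule != "all_H_to_D":
            raise ValueError(f"unknown isotope rule {rule!r}")
        selected = {m.label for m in spectrum.modes if m.involves_hydrogen}
    else:
        selected = set(rule)
        unknown = selected - {m.label for m in spectrum.modes}
        if unknown:
            raise ValueError(f"isotope rule names unknown mode labels: {sorted(unknown)}")

    def factor_for(mode: VibrationalMode) -> IsotopeFactor:
        if model == "reduced_mass":
            if mode.reduced_mass is None:
                raise ValueError(
                    f"mode {mode.label!r} has no reduced mass; cannot use reduced_mass model"
                )
            # interpret the stored reduced mass as the heavy-partner mass
            return isotope_frequency_factor(
                "reduced_mass", mass_original, mass_substituted, partner_mass=mode.reduced_mass
            )
        return isotope_frequency_factor(model, mass_original, mass_substituted)

    new_modes = tuple(
        replace(m, frequency=m.frequency * factor_for(m).ratio) if m.label in selected else m
        for m in spectrum.modes
    )
    return OdorantSpectrum(
        name=spectrum.name + "-D" if selected else spectrum.name,
        modes=new_modes,
        metadata=dict(spectrum.metadata),
    )


def isotope_discrimination(
    spectrum: OdorantSpectrum,
    receptors: Sequence[ReceptorDefinition],
    model: str = "proton_only",
) -> tuple[bool, str | None]:
    """Is an odorant distinguishable from its fully deuterated counterpart?

    Compares the activation rows of the spectrum and its H→D substituted
    version; returns (discriminated, name of the first receptor whose
    response differs, or None).
    """
    if not receptors:
        return False, None
    deuterated = apply_isotope_substitution(spectrum, "all_H_to_D", model=model)
    for receptor in receptors:
        a = receptor_activation(spectrum, receptor).activated
        b = receptor_activation(deuterated, receptor).activated
        if a != b:
            return True, receptor.name
    return False, None


def generate_synthetic_spectrum(
    n_modes: int,
    bands: Sequence[tuple[float, float]] = ((500.0, 1800.0), (2400.0, 3200.0)),
    s_range: tuple[float, float] = (0.01, 0.3),
    h_fraction: float = 0.5,
    seed: int = 0,
    name: str = "synthetic",
) -> OdorantSpectrum:
    """Reproducible synthetic odorant spectrum for fixtures and demos.

    Frequencies are uniform over the union of ``bands`` (bands chosen with
    probability proportional to width), couplings uniform in ``s_range``, and
    each mode carries a hydrogen flag with probability ``h_fraction``.  The
    default bands mimic a small organic odorant: a fingerprint region and a
    stretch region.  Identical seeds give identical spectra.
    """
    if not bands:
        raise ValueError("need at least one frequency band")
    for lo, hi in bands:
        if not (0 < lo < hi):
            raise ValueError(f"invalid band ({lo}, {hi})")
    if n_modes < 0:
        raise ValueError("n_modes must be non-negative")
    rng = np.random.default_rng(seed)
    widths = np.array([hi - lo for lo, hi in bands], dtype=float)
    probs = widths / widths.sum()
    modes = []
    for i in range(n_modes):
        b = int(rng.choice(len(bands), p=probs))
        lo, hi = bands[b]
        modes.append(
            VibrationalMode(
                label=f"m{i:03d}",
                frequency=float(rng.uniform(lo, hi)),
                huang_rhys=float(rng.uniform(*s_range)),
                involves_hydrogen=bool(rng.random() < h_fraction),
            )
        )
    return OdorantSpectrum(name=name, modes=tuple(modes), metadata={"seed": seed})
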