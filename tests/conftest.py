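import pytest

from oriet import (
    OdorantSpectrum,
    ReceptorDefinition,
    ReceptorParams,
    VibrationalMode,
)


@pytest.fixture
def default_params() -> ReceptorParams:
    """The representative receptor operating point (tuned, 200 meV quantum)."""
    return ReceptorParams()


@pytest.fixture
def sulphur_receptor() -> ReceptorDefinition:
    """A sulphuraceous receptor tuned to the S-H stretch region, 2600 +/- 25 cm^-1."""
    return ReceptorDefinition(name="sulphur", tuned_frequency=2600.0, resolution_window=25.0)


@pytest.fixture
def h2s_spectrum() -> OdorantSpectrum:
    """Hydrogen-sulphide-like odorant: an S-H stretch at 2600 cm^-1."""
    return OdorantSpectrum(
        name="h2s",
        modes=(
            VibrationalMode("bend", 1180.0, 0.05, involves_hydrogen=True),
            VibrationalMode("sh_stretch", 2600.0, 0.1, involves_hydrogen=True),
        ),
    )


@pytest.fixture
def decaborane_spectrum() -> OdorantSpectrum:
    """Decaborane-like odorant: strongest B-H stretch 25 cm^-1 from the S-H stretch."""
    return OdorantSpectrum(
        name="decaborane",
        modes=(
            VibrationalMode("cage", 780.0, 0.08),
            VibrationalMode("bh_stretch", 2575.0, 0.12, involves_hydrogen=True),
        ),
    )
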