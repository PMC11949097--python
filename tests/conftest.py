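import numpy as np
import pytest

from photonmu import (
    CrossSectionProvider,
    MaterialComposition,
    load_reference,
    load_tissue,
)
from photonmu.constants import AVOGADRO
from photonmu.materials import ELEMENTS


@pytest.fixture(scope="session")
def water():
    return load_tissue("Water")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture
def pure_hydrogen():
    return MaterialComposition("Hydrogen", density=1.0, fractions={"H": 1.0})


def constant_provider(sigma_cm2: float, transfer_ratio: float = 0.5,
                      channel: str = "photoelectric") -> CrossSectionProvider:
    """Energy-independent synthetic cross section, same for every element."""
    return CrossSectionProvider(
        channel=channel,
        evaluate=lambda sym, E: sigma_cm2,
        transfer_evaluate=lambda sym, E: sigma_cm2 * transfer_ratio,
        provenance="analytic",
    )


def sigma_macroscopic(mat: MaterialComposition, sigma_cm2: float) -> float:
    """Macroscopic cross section (1/cm) of a constant per-atom cross section."""
    per_gram = sum(
        w * AVOGADRO / ELEMENTS[s].A * sigma_cm2 for s, w in mat.fractions.items()
    )
    return per_gram * mat.density
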