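import numpy as np
import pytest

from g4screen.constants import DELTA_NH4, PROTON_MASS
from g4screen.masses import Ligand, Oligo, oligo_neutral_mass


@pytest.fixture(scope="session")
def tg4t_tetramer() -> Oligo:
    """The (dTG4T)4 tetramolecular G4 used as external CCS calibrant."""
    return Oligo("TG4T", "TGGGGT", strand_count=4)


@pytest.fixture(scope="session")
def qqpq() -> Ligand:
    """QQPQ foldamer stand-in; mass is plumbing, not a measured value."""
    return Ligand("QQPQ", neutral_mass=950.0, charge_sites=3)


def calibrant_ion_mass(oligo: Oligo, z: int, n_nh4: int = 3) -> float:
    """Mass of the [(dTG4T)4 + n NH4 - (n+z) H]z- ion."""
    return oligo_neutral_mass(oligo) + n_nh4 * DELTA_NH4 - z * PROTON_MASS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
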