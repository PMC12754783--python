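"""Mass and m/z arithmetic for oligonucleotides, foldamer ligands, and
their adducted negative ions.

A strand is treated with the 5'-OH / 3'-OH convention standard for
synthesized oligonucleotides: n nucleosides joined by (n-1) phosphodiester
bridges, each bridge adding HPO3 and condensing out one water. Multimeric
targets (dimers, tetramers) multiply the single-strand mass by
``strand_count``; cation adducts replace protons (negative mode).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional

from .constants import (
    ATOMIC_MASS_AVERAGE,
    ATOMIC_MASS_MONO,
    DELTA_K,
    DELTA_NH4,
    PROTON_MASS,
)

MassMode = Literal["average", "monoisotopic"]

# 2'-deoxyribonucleoside elemental compositions (free nucleoside, no phosphate).
NUCLEOSIDE_FORMULA: dict[str, dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 3},
    "C": {"C": 9, "H": 13, "N": 3, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 4},
    "T": {"C": 10, "H": 14, "N": 2, "O": 5},
}

_BRIDGE = {"H": -1, "O": 2, "P": 1}  # +HPO3 - H2O per phosphodiester


@dataclass(frozen=True)
class Oligo:
    """A DNA target: single sequence plus strand multiplicity (1, 2, or 4)."""

    name: str
    sequence: str
    strand_count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in NUCLEOSIDE_FORMULA:
                raise ValueError(
                    f"oligo {self.name!r}: invalid character {ch!r} at position {i}"
                )
        if self.strand_count < 1:
            raise ValueError("strand_count must be >= 1")


@dataclass(frozen=True)
class Ligand:
    """A foldamer ligand; the neutral mass is user input (no formula inference)."""

    name: str
    neutral_mass: float
    charge_sites: int = 0

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError("ligand neutral_mass must be positive")
        if self.charge_sites < 0:
            raise ValueError("charge_sites must be >= 0")


@dataclass(frozen=True)
class SpeciesKey:
    """Identity of one ion species: target, ligand count (0=M, 1=ML, 2=ML2),
    adduct counts, and charge magnitude z (negative mode)."""

    target: Oligo
    ligand_count: int = 0
    k_count: int = 0
    nh4_count: int = 0
    charge_magnitude: int = 1

    def __post_init__(self):
        if min(self.ligand_count, self.k_count, self.nh4_count) < 0:
            raise ValueError("counts must be >= 0")
        if self.charge_magnitude < 1:
            raise ValueError("charge magnitude z must be >= 1")

    @property
    def stoichiometry_label(self) -> str:
        return {0: "M", 1: "ML", 2: "ML2"}.get(
            self.ligand_count, f"ML{self.ligand_count}"
        )


def strand_formula(sequence: str) -> Counter:
    """Elemental composition of one 5'-OH/3'-OH strand."""
    comp: Counter = Counter()
    for ch in sequence:
        comp.update(NUCLEOSIDE_FORMULA[ch])
    n = len(sequence)
    for el, k in _BRIDGE.items():
        comp[el] += k * (n - 1)
    return comp


def oligo_neutral_mass(oligo: Oligo, mode: MassMode = "average") -> float:
    """Neutral mass (Da) of the full assembly: strand mass x strand_count."""
    table = ATOMIC_MASS_AVERAGE if mode == "average" else ATOMIC_MASS_MONO
    comp = strand_formula(oligo.sequence)
    strand = sum(table[el] * k for el, k in comp.items())
    return strand * oligo.strand_count


def species_mz(
    key: SpeciesKey, ligand: Optional[Ligand] = None, mode: MassMode = "average"
) -> float:
    """m/z (Th) of a deprotonated negative ion with K+/NH4+ adducts.

    m/z = (M + nL*ML + nK*dK + nNH4*dNH4 - z*mH) / z with each cation
    replacing one proton and z further protons removed for the charge.
    """
    if key.ligand_count > 0 and ligand is None:
        raise ValueError("ligand mass required for complexed species")
    m = oligo_neutral_mass(key.target, mode)
    if ligand is not None:
        m += key.ligand_count * ligand.neutral_mass
    m += key.k_count * DELTA_K + key.nh4_count * DELTA_NH4
    z = key.charge_magnitude
    return (m - z * PROTON_MASS) / z
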