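"""Sequential-binding (1:1 then 2:1) screening mathematics.

Concentrations of M, ML, ML2 follow from relative intensities and the total
DNA concentration; free ligand by mass-balance difference; the two
macroscopic dissociation constants are

    KD1 = [M][L]/[ML]        KD2 = [ML][L]/[ML2]

and the fraction of bound DNA is (ML + ML2) / (M + ML + ML2). For two
identical independent sites with microscopic constant kd the macroscopic
constants are KD1 = kd/2 and KD2 = 2 kd, so KD2/KD1 = 4 is the
non-cooperative boundary: KD2 < 4 KD1 is positive cooperativity,
KD2 > 4 KD1 negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .spectra import SpeciesTable

COOP_EPS = 1e-6  # relative width of the non-cooperative band at KD2 = 4 KD1


@dataclass(frozen=True)
class Censored:
    """A one-sided bound on a quantity that could not be determined as a
    point value (species below the detection floor, or ligand exhausted)."""

    bound: float
    direction: str  # "above": true value > bound; "below": true value < bound

    def __post_init__(self):
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")

    def __repr__(self):
        sym = ">" if self.direction == "above" else "<"
        return f"KD {sym} {self.bound:.3g}"


KDValue = Union[float, Censored]


@dataclass(frozen=True)
class BindingSample:
    """Composition of one screening sample (concentrations in micromolar)."""

    M0: float
    L0: float
    standard_conc: float = 4.0  # dT6 internal standard
    electrolyte: str = "0.5 mM KCl + 100 mM TMAA"

    def __post_init__(self):
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")
        if self.L0 < 0:
            raise ValueError("L0 must be non-negative")


@dataclass(frozen=True)
class EquilibriumState:
    free_M: float
    free_L: float
    ML: float
    ML2: float

    def __post_init__(self):
        if min(self.free_M, self.free_L, self.ML, self.ML2) < -1e-12:
            raise ValueError("concentrations must be non-negative")

    @property
    def M0(self) -> float:
        return self.free_M + self.ML + self.ML2

    @property
    def L0(self) -> float:
        return self.free_L + self.ML + 2.0 * self.ML2


@dataclass
class BindingResult:
    KD1: Optional[KDValue]
    KD2: Optional[KDValue]
    fraction_bound: Optional[float]
    cooperativity: str = "undetermined"


def concentrations_from_intensities(
    table_or_triplet, sample: BindingSample
) -> Optional[tuple[float, float, float]]:
    """Apportion total DNA over M/ML/ML2 by relative corrected intensity.

    Returns None (undetermined) when every intensity is zero."""
    if isinstance(table_or_triplet, SpeciesTable):
        i_m, i_ml, i_ml2 = table_or_triplet.intensity_triplet()
    else:
        i_m, i_ml, i_ml2 = table_or_triplet
    total = i_m + i_ml + i_ml2
    if total <= 0:
        return None
    return (
        sample.M0 * i_m / total,
        sample.M0 * i_ml / total,
        sample.M0 * i_ml2 / total,
    )


def free_ligand(sample: BindingSample, ML: float, ML2: float) -> Union[float, Censored]:
    """[L] = [L]0 - [ML] - 2[ML2]; non-positive results are censored rather
    than returned as unphysical negative concentrations."""
    L = sample.L0 - ML - 2.0 * ML2
    if L <= 0:
        return Censored(bound=0.0, direction="below")
    return L


def fraction_bound(M: float, ML: float, ML2: float) -> Optional[float]:
    total = M + ML + ML2
    if total <= 0:
        return None
    return (ML + ML2) / total


def classify_cooperativity(KD1: Optional[KDValue], KD2: Optional[KDValue]) -> str:
    """Compare KD2 against the statistical-factor boundary 4*KD1."""
    if not isinstance(KD1, (int, float)) or not isinstance(KD2, (int, float)):
        return "undetermined"
    boundary = 4.0 * KD1
    if KD2 < boundary * (1.0 - COOP_EPS):
        return "positive"
    if KD2 > boundary * (1.0 + COOP_EPS):
        return "negative"
    return "non-cooperative"


def kd_single_point(
    M: float,
    ML: float,
    ML2: float,
    L: Union[float, Censored],
    detection_floor: float = 1e-3,
) -> BindingResult:
    """Single-concentration KD estimates from one speciation measurement.

    Zero denominators produce one-sided bounds using ``detection_floor``
    (micromolar) as the pseudo-concentration of the undetected species.
    """
    if min(M, ML, ML2) < 0:
        raise ValueError("concentrations must be non-negative")
    fb = fraction_bound(M, ML, ML2)
    if isinstance(L, Censored):
        # ligand exhausted: KDs can only be bounded from below using the floor
        kd1 = (
            Censored(M * detection_floor / ML, "below") if ML > 0 else None
        )
        kd2 = (
            Censored(ML * detection_floor / ML2, "below") if ML2 > 0 else None
        )
        return BindingResult(kd1, kd2, fb, "undetermined")
    kd1: Optional[KDValue]
    kd2: Optional[KDValue]
    if ML > 0:
        kd1 = M * L / ML
    elif M > 0 and L > 0:
        kd1 = Censored(M * L / detection_floor, "above")
    else:
        kd1 = None
    if ML2 > 0:
        kd2 = ML * L / ML2
    elif ML > 0 and L > 0:
        kd2 = Censored(ML * L / detection_floor, "above")
    else:
        kd2 = None
    return BindingResult(kd1, kd2, fb, classify_cooperativity(kd1, kd2))


def solve_equilibrium(
    sample: BindingSample, KD1: float, KD2: float
) -> EquilibriumState:
    """Forward model: unique speciation satisfying both mass balances and
    both KD definitions, by bracketed root-finding on free ligand.

    At free ligand x the DNA partitions as
        M = M0 / (1 + x/KD1 + x^2/(KD1 KD2)),
    and bound ligand ML + 2 ML2 is strictly increasing in x, so
    g(x) = x + ML + 2 ML2 - L0 has exactly one root in [0, L0].
    """
    if KD1 <= 0 or KD2 <= 0:
        raise ValueError("dissociation constants must be positive")
    M0, L0 = sample.M0, sample.L0
    if L0 == 0:
        return EquilibriumState(free_M=M0, free_L=0.0, ML=0.0, ML2=0.0)

    def speciate(x: float):
        m = M0 / (1.0 + x / KD1 + x * x / (KD1 * KD2))
        ml = m * x / KD1
        ml2 = ml * x / KD2
        return m, ml, ml2

    def g(x: float) -> float:
        _, ml, ml2 = speciate(x)
        return x + ml + 2.0 * ml2 - L0

    if g(L0) < 0:  # cannot happen mathematically; guard for roundoff
        x = L0
    else:
        x = brentq(g, 0.0, L0, xtol=1e-15, rtol=1e-15, maxiter=200)
    m, ml, ml2 = speciate(x)
    state = EquilibriumState(free_M=m, free_L=x, ML=ml, ML2=ml2)
    if abs(state.M0 - M0) > 1e-9 * M0 or abs(state.L0 - L0) > 1e-9 * L0:
        raise RuntimeError(
            f"equilibrium solver failed mass balance: M={state.M0} vs {M0}, "
            f"L={state.L0} vs {L0}"
        )
    return state


def screen_panel(
    samples: Sequence[dict],
) -> tuple[pd.DataFrame, dict[tuple[str, str], BindingResult]]:
    """Assemble the screening heatmap: rows = DNA, columns = foldamer,
    values = fraction of DNA bound; a BindingResult is attached per cell.

    Each sample dict needs keys: dna, foldamer, sample (BindingSample), and
    either table (SpeciesTable) or intensities ((I_M, I_ML, I_ML2)).
    All-zero intensities yield an absent (NaN) cell, not zero.
    """
    if not samples:
        raise ValueError("at least one sample required")
    results: dict[tuple[str, str], BindingResult] = {}
    dnas, folds = [], []
    for s in samples:
        dna, fold = s["dna"], s["foldamer"]
        if dna not in dnas:
            dnas.append(dna)
        if fold not in folds:
            folds.append(fold)
        conc = concentrations_from_intensities(
            s.get("table", s.get("intensities")), s["sample"]
        )
        if conc is None:
            results[(dna, fold)] = BindingResult(None, None, None, "undetermined")
            continue
        M, ML, ML2 = conc
        L = free_ligand(s["sample"], ML, ML2)
        results[(dna, fold)] = kd_single_point(M, ML, ML2, L)
    heat = pd.DataFrame(np.nan, index=dnas, columns=folds, dtype=float)
    for (dna, fold), res in results.items():
        if res.fraction_bound is not None:
            heat.loc[dna, fold] = res.fraction_bound
    return heat, results
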