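"""Spectrum ingestion, window integration, and noise-corrected species tables.

The quantification step mirrors standard native-MS practice: integrate all
signal in an m/z window per ion species, estimate the per-point noise sigma
in a blank region, subtract three sigma (scaled by sqrt of the number of
summed points) from each integrated signal, and aggregate the K+/NH4+
adduct ladder and monitored charge states per binding stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import mzml
from .masses import Ligand, SpeciesKey, species_mz


@dataclass
class MassSpectrum:
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    sample_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("empty spectrum")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SpeciesWindow:
    key: SpeciesKey
    center: float
    half_width: float

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class SpeciesTable:
    """Background-corrected intensities per species for one sample."""

    entries: dict[SpeciesKey, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    internal_standard_intensity: float = 0.0
    ambiguous: list[SpeciesKey] = field(default_factory=list)

    def stoichiometry_totals(self) -> dict[int, float]:
        """Sum over the adduct ladder and charge states per ligand count."""
        totals: dict[int, float] = {}
        for key, val in self.entries.items():
            totals[key.ligand_count] = totals.get(key.ligand_count, 0.0) + val
        return totals

    def intensity_triplet(self) -> tuple[float, float, float]:
        """(I_M, I_ML, I_ML2) totals; higher stoichiometries fold into ML2."""
        totals = self.stoichiometry_totals()
        i_m = totals.get(0, 0.0)
        i_ml = totals.get(1, 0.0)
        i_ml2 = sum(v for k, v in totals.items() if k >= 2)
        return i_m, i_ml, i_ml2


def read_spectrum(path, format: str = "table") -> MassSpectrum:
    """Read a spectrum from an mzML file or a two-column m/z-intensity table.

    Tables may be whitespace- or comma-delimited; lines starting with '#'
    are ignored. Profile data pass through unmodified.
    """
    if format == "mzml":
        mz, intensity = mzml.read_mzml(path)
    elif format == "table":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise ValueError(f"{path}: malformed line {line!r}")
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    # tolerate a single header line
                    if rows:
                        raise
                    continue
        if not rows:
            raise ValueError(f"{path}: no data rows")
        arr = np.asarray(rows)
        mz, intensity = arr[:, 0], arr[:, 1]
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    return MassSpectrum(mz=mz, intensity=intensity, sample_id=str(path))


def write_table(path, spec: MassSpectrum) -> None:
    np.savetxt(path, np.column_stack([spec.mz, spec.intensity]), fmt="%.8f %.8f")


def integrate_window(spec: MassSpectrum, w: SpeciesWindow) -> float:
    """Trapezoidal area of the profile signal over [center-hw, center+hw].

    A window with no overlap returns 0 with a warning, not an error."""
    lo, hi = w.center - w.half_width, w.center + w.half_width
    if hi < spec.mz[0] or lo > spec.mz[-1]:
        warnings.warn(f"window [{lo:.2f}, {hi:.2f}] outside spectrum range")
        return 0.0
    grid = np.clip(spec.mz, lo, hi)
    # interpolate intensity at the clipped boundaries for an exact trapezoid
    mask = (spec.mz >= lo) & (spec.mz <= hi)
    xs = spec.mz[mask]
    ys = spec.intensity[mask]
    if lo > spec.mz[0]:
        xs = np.concatenate([[lo], xs])
        ys = np.concatenate([[np.interp(lo, spec.mz, spec.intensity)], ys])
    if hi < spec.mz[-1]:
        xs = np.concatenate([xs, [hi]])
        ys = np.concatenate([ys, [np.interp(hi, spec.mz, spec.intensity)]])
    if xs.size < 2:
        return 0.0
    return float(np.trapezoid(ys, xs))


def window_point_count(spec: MassSpectrum, w: SpeciesWindow) -> int:
    lo, hi = w.center - w.half_width, w.center + w.half_width
    return int(np.count_nonzero((spec.mz >= lo) & (spec.mz <= hi)))


def estimate_noise(
    spec: MassSpectrum,
    blank_region: tuple[float, float],
    species_windows: Sequence[SpeciesWindow] = (),
) -> float:
    """Standard deviation of intensities inside a species-free m/z region."""
    lo, hi = blank_region
    for w in species_windows:
        if w.center + w.half_width >= lo and w.center - w.half_width <= hi:
            raise ValueError("blank region overlaps an assigned species window")
    mask = (spec.mz >= lo) & (spec.mz <= hi)
    if np.count_nonzero(mask) < 10:
        raise ValueError("blank region must contain at least 10 points")
    return float(np.std(spec.intensity[mask]))


def correct_intensity(raw: float, sigma: float, n_points: int = 1) -> float:
    """Subtract 3 sigma of summed noise (sigma * sqrt(n)) and clamp at zero."""
    if raw < 0 or sigma < 0:
        raise ValueError("raw intensity and sigma must be non-negative")
    return max(raw - 3.0 * sigma * np.sqrt(max(n_points, 1)), 0.0)


def default_windows(
    keys: Iterable[SpeciesKey],
    ligand: Optional[Ligand] = None,
    half_width: float = 1.0,
    mode: str = "average",
) -> list[SpeciesWindow]:
    """Windows centered at each species m/z; width scales with the unresolved
    isotope envelope (wider at low charge where the envelope is wider in Th)."""
    out = []
    for key in keys:
        hw = half_width * max(1.0, 4.0 / key.charge_magnitude)
        out.append(
            SpeciesWindow(key=key, center=species_mz(key, ligand, mode), half_width=hw)
        )
    return out


def build_species_table(
    spec: MassSpectrum,
    keys: Sequence[SpeciesKey],
    ligand: Optional[Ligand] = None,
    tolerance: float = 1.0,
    half_width: float = 1.0,
    noise_sigma: float = 0.0,
    standard_window: Optional[SpeciesWindow] = None,
    mode: str = "average",
) -> SpeciesTable:
    """Integrate every species window, noise-correct, and tabulate.

    Windows of different ligand_count whose centers are closer than
    ``tolerance`` are mutually ambiguous: excluded from the table, flagged,
    and logged via warnings rather than split.
    """
    windows = default_windows(keys, ligand, half_width, mode)
    ambiguous: set[SpeciesKey] = set()
    for i, wi in enumerate(windows):
        for wj in windows[i + 1 :]:
            if (
                wi.key.ligand_count != wj.key.ligand_count
                and abs(wi.center - wj.center) < tolerance
            ):
                ambiguous.update((wi.key, wj.key))
                warnings.warn(
                    f"ambiguous overlap between {wi.key.stoichiometry_label} and "
                    f"{wj.key.stoichiometry_label} near {wi.center:.2f} Th; excluded"
                )
    table = SpeciesTable(noise_sigma=noise_sigma, ambiguous=sorted(
        ambiguous, key=lambda k: (k.ligand_count, k.k_count, k.nh4_count,
                                  k.charge_magnitude)))
    for w in windows:
        if w.key in ambiguous:
            continue
        raw = integrate_window(spec, w)
        n = window_point_count(spec, w)
        table.entries[w.key] = correct_intensity(raw, noise_sigma, n)
    if standard_window is not None:
        raw = integrate_window(spec, standard_window)
        n = window_point_count(spec, standard_window)
        table.internal_standard_intensity = correct_intensity(raw, noise_sigma, n)
    return table
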