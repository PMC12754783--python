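"""Stepped-field drift-tube ion mobility: reduced mobility from arrival
times at several drift voltages, collision cross sections via the
Mason-Schamp relation, calibrant validation, and CCS-distribution
reconstruction.

The arrival time obeys

    t_A = t0 + (L^2 p T0) / (K0 p0 T) * 1/dV

so a linear fit of apex arrival time against the reduced inverse voltage
x = L^2 p T0 / (p0 T dV) gives 1/K0 as the slope and the dead time t0 as
the intercept. K0 then converts to a cross section through

    CCS = (3/16) * z e / (N0 K0) * sqrt(2 pi / (mu kB T))

with mu the ion-helium reduced mass and N0 the Loschmidt number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    BOLTZMANN,
    DA_TO_KG,
    ELEMENTARY_CHARGE,
    HELIUM_MASS,
    N0_LOSCHMIDT,
    P0_TORR,
    T0_K,
)

DRIFT_TUBE_LENGTH_CM = 78.1


@dataclass
class DriftRecord:
    """One arrival-time distribution at a fixed drift voltage."""

    arrival_ms: np.ndarray
    intensity: np.ndarray
    delta_V: float
    pressure_torr: float
    temperature_K: float

    def __post_init__(self):
        self.arrival_ms = np.asarray(self.arrival_ms, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arrival_ms.shape != self.intensity.shape:
            raise ValueError("arrival axis and intensity must have equal length")
        if np.any(np.diff(self.arrival_ms) <= 0):
            raise ValueError("arrival axis must be strictly increasing")
        if self.delta_V <= 0 or self.pressure_torr <= 0 or self.temperature_K <= 0:
            raise ValueError("delta_V, pressure and temperature must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class SteppedFieldFit:
    K0: float  # cm^2 V^-1 s^-1
    t0_ms: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.K0 <= 0:
            raise ValueError(f"fitted K0 must be positive (got {self.K0:.4g})")
        if self.n_points < 2:
            raise ValueError("stepped-field fit needs >= 2 voltages")


@dataclass
class CCSResult:
    ccs: float  # square angstrom
    z: int
    ion_mass: float  # Da
    gas_mass: float = HELIUM_MASS

    def __post_init__(self):
        if self.ccs <= 0:
            raise ValueError("ccs must be positive")


def apex_time(record: DriftRecord) -> float:
    """Apex arrival time via parabolic interpolation around the maximum bin."""
    i = int(np.argmax(record.intensity))
    t, y = record.arrival_ms, record.intensity
    if i == 0 or i == t.size - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    # bins may be non-uniform; use local spacing
    dt = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + 0.5 * (y0 - y2) / denom * dt)


def reduced_inverse_voltage(record: DriftRecord, length_cm: float) -> float:
    """x = L^2 p T0 / (p0 T dV); units: cm^2 V^-1 scaled by dimensionless
    pressure/temperature normalization, so t = x / K0 is in seconds."""
    return (
        length_cm**2
        * record.pressure_torr
        * T0_K
        / (P0_TORR * record.temperature_K * record.delta_V)
    )


def fit_stepped_field(
    records: Sequence[DriftRecord],
    length_cm: float = DRIFT_TUBE_LENGTH_CM,
    pt_tolerance: float = 0.05,
) -> SteppedFieldFit:
    """Linear fit of apex arrival times against the reduced inverse voltage."""
    if len(records) < 2:
        raise ValueError("need records at >= 2 distinct drift voltages")
    ps = np.array([r.pressure_torr for r in records])
    ts = np.array([r.temperature_K for r in records])
    if np.ptp(ps) / ps.mean() > pt_tolerance or np.ptp(ts) / ts.mean() > pt_tolerance:
        raise ValueError("pressure/temperature inconsistent across records")
    x = np.array([reduced_inverse_voltage(r, length_cm) for r in records])
    if np.unique([r.delta_V for r in records]).size < 2:
        raise ValueError("need >= 2 distinct drift voltages")
    y = np.array([apex_time(r) for r in records]) * 1e-3  # s
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError(
            f"negative or zero fitted mobility slope ({slope:.4g}); check inputs"
        )
    pred = intercept + slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SteppedFieldFit(
        K0=1.0 / slope, t0_ms=intercept * 1e3, r_squared=r2, n_points=len(records)
    )


def _mu_kg(ion_mass: float, gas_mass: float) -> float:
    return ion_mass * gas_mass / (ion_mass + gas_mass) * DA_TO_KG


def mason_schamp(
    K0: float, z: int, ion_mass: float, T: float, gas_mass: float = HELIUM_MASS
) -> float:
    """CCS (square angstrom) from reduced mobility (cm^2 V^-1 s^-1)."""
    if min(K0, z, ion_mass, T) <= 0:
        raise ValueError("all arguments must be positive")
    mu = _mu_kg(ion_mass, gas_mass)
    k0_si = K0 * 1e-4  # m^2 V^-1 s^-1
    ccs_m2 = (
        (3.0 / 16.0)
        * z
        * ELEMENTARY_CHARGE
        / (N0_LOSCHMIDT * k0_si)
        * np.sqrt(2.0 * np.pi / (mu * BOLTZMANN * T))
    )
    return float(ccs_m2 * 1e20)


def invert_mason_schamp(
    ccs: float, z: int, ion_mass: float, T: float, gas_mass: float = HELIUM_MASS
) -> float:
    """Reduced mobility (cm^2 V^-1 s^-1) that reproduces a target CCS."""
    if min(ccs, z, ion_mass, T) <= 0:
        raise ValueError("all arguments must be positive")
    mu = _mu_kg(ion_mass, gas_mass)
    k0_si = (
        (3.0 / 16.0)
        * z
        * ELEMENTARY_CHARGE
        / (N0_LOSCHMIDT * ccs * 1e-20)
        * np.sqrt(2.0 * np.pi / (mu * BOLTZMANN * T))
    )
    return float(k0_si * 1e4)


def validate_calibrant(
    measured_ccs: float, reference_ccs: float, tolerance: float = 0.02
) -> tuple[bool, float]:
    """Instrument-settings check: pass iff the relative deviation from the
    published reference CCS is within tolerance (default 2%)."""
    if measured_ccs <= 0 or reference_ccs <= 0:
        raise ValueError("CCS values must be positive")
    rel = abs(measured_ccs - reference_ccs) / reference_ccs
    return rel <= tolerance, rel


def ccs_distribution(
    record: DriftRecord,
    fit: SteppedFieldFit,
    z: int,
    ion_mass: float,
    length_cm: float = DRIFT_TUBE_LENGTH_CM,
    gas_mass: float = HELIUM_MASS,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform one arrival-time distribution onto a CCS axis.

    Each time maps through K0(t) = x / (t - t0) to a cross section; the
    abundance is rescaled by the Jacobian |dt/dCCS| so integrated area is
    preserved. Points at or before the dead time are dropped with a warning.
    """
    x = reduced_inverse_voltage(record, length_cm)
    t_s = record.arrival_ms * 1e-3
    t0_s = fit.t0_ms * 1e-3
    mask = t_s > t0_s
    if not np.all(mask):
        warnings.warn(
            f"dropping {np.count_nonzero(~mask)} arrival points at or before "
            "the dead time t0"
        )
    t_s = t_s[mask]
    inten = record.intensity[mask]
    if t_s.size < 2:
        raise ValueError("too few arrival points beyond the dead time")
    k0 = x / (t_s - t0_s)
    ccs = np.array(
        [mason_schamp(k, z, ion_mass, record.temperature_K, gas_mass) for k in k0]
    )
    # monotone increasing in t; Jacobian dt/dCCS from the numerical gradient
    jac = np.gradient(t_s, ccs)
    abundance = inten * np.abs(jac)
    return ccs, abundance
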