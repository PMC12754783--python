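"""CD and UV-melting curve processing.

Ellipticity in millidegrees converts to molar ellipticity via
Delta-eps = theta / (32980 c l); melting absorbance converts to folded
fraction theta(T) = (L0(T) - A(T)) / (L0(T) - L1(T)) with affine baselines
for the unfolded (L0) and folded (L1) states, and the melting temperature
is the first theta = 0.5 crossing. Ligand-induced stabilization is the
signed difference of melting temperatures with and without ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import CD_CONVERSION

R_SQUARED_WARN = 0.9


@dataclass
class CDSpectrum:
    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    c_molar: float
    path_cm: float
    blank_mdeg: Optional[np.ndarray] = None

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength axis must be ascending")
        if self.c_molar <= 0 or self.path_cm <= 0:
            raise ValueError("concentration and path length must be positive")


@dataclass
class MeltingCurve:
    temperature_C: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: int = 295
    direction: str = "heating"
    ramp_rate: float = 0.2  # degC / min
    reference_absorbance: Optional[np.ndarray] = None  # 335 nm drift channel

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        d = np.diff(self.temperature_C)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperature must be monotone within a ramp")
        if self.wavelength_nm not in (260, 295, 335):
            raise ValueError("monitored wavelength must be 260, 295 or 335 nm")
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")

    def drift_corrected(self) -> np.ndarray:
        """Absorbance minus the 335 nm internal-reference channel."""
        if self.reference_absorbance is None:
            return self.absorbance
        return self.absorbance - np.asarray(self.reference_absorbance, dtype=float)


@dataclass
class Baselines:
    """Affine baselines (intercept, slope) for the unfolded (L0) and folded
    (L1) states."""

    L0: tuple[float, float]
    L1: tuple[float, float]
    r_squared_low: float = 1.0
    r_squared_high: float = 1.0

    def l0_at(self, T):
        return self.L0[0] + self.L0[1] * np.asarray(T, dtype=float)

    def l1_at(self, T):
        return self.L1[0] + self.L1[1] * np.asarray(T, dtype=float)


@dataclass
class FoldedFractionCurve:
    temperature_C: np.ndarray
    theta: np.ndarray
    baselines: Baselines
    direction: str = "heating"


@dataclass
class MeltingResult:
    t_m: Optional[float]
    theta_range: tuple[float, float] = (0.0, 1.0)
    multimodal: bool = False

    @property
    def defined(self) -> bool:
        return self.t_m is not None


def molar_ellipticity(spec: CDSpectrum) -> np.ndarray:
    """Delta-epsilon (M^-1 cm^-1), blank-subtracted point-wise."""
    theta = spec.ellipticity_mdeg
    if spec.blank_mdeg is not None:
        theta = theta - np.asarray(spec.blank_mdeg, dtype=float)
    return theta / (CD_CONVERSION * spec.c_molar * spec.path_cm)


def _linfit(T: np.ndarray, A: np.ndarray) -> tuple[tuple[float, float], float]:
    slope, intercept = np.polyfit(T, A, 1)
    pred = intercept + slope * T
    ss_tot = float(np.sum((A - A.mean()) ** 2))
    r2 = 1.0 - float(np.sum((A - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return (float(intercept), float(slope)), r2


def fit_baselines(
    curve: MeltingCurve,
    low_window: Optional[tuple[float, float]] = None,
    high_window: Optional[tuple[float, float]] = None,
    window_fraction: float = 0.15,
) -> Baselines:
    """Affine fits in the low- and high-temperature flanks.

    Default windows are the lowest and highest 15% of the temperature span.
    Which flank is folded depends on the monitored wavelength: at 295 nm
    the folded G4 absorbs more, so the low-T flank is the folded baseline
    L1; at 260 nm the convention inverts (unfolded absorbs more).
    """
    T = curve.temperature_C
    A = curve.drift_corrected()
    tmin, tmax = float(T.min()), float(T.max())
    span = tmax - tmin
    if low_window is None:
        low_window = (tmin, tmin + window_fraction * span)
    if high_window is None:
        high_window = (tmax - window_fraction * span, tmax)
    if low_window[1] > high_window[0]:
        raise ValueError("baseline windows overlap")
    low_mask = (T >= low_window[0]) & (T <= low_window[1])
    high_mask = (T >= high_window[0]) & (T <= high_window[1])
    if np.count_nonzero(low_mask) < 5 or np.count_nonzero(high_mask) < 5:
        raise ValueError("each baseline window needs >= 5 points")
    low_fit, r2_low = _linfit(T[low_mask], A[low_mask])
    high_fit, r2_high = _linfit(T[high_mask], A[high_mask])
    # flag windows that caught transition signal: residuals large relative to
    # the full melting amplitude (plain R^2 misfires on flat noisy baselines)
    span = float(np.ptp(A))
    for name, fit_, mask in (("low-T", low_fit, low_mask),
                             ("high-T", high_fit, high_mask)):
        resid = A[mask] - (fit_[0] + fit_[1] * T[mask])
        if span > 0 and np.std(resid) > 0.05 * span:
            warnings.warn(
                f"poor {name} baseline fit (residual {np.std(resid):.3g} vs "
                f"melting amplitude {span:.3g}); window may overlap the "
                "transition"
            )
    if curve.wavelength_nm == 295:
        # folded species absorbs higher: low-T flank = folded (L1)
        return Baselines(L0=high_fit, L1=low_fit,
                         r_squared_low=r2_low, r_squared_high=r2_high)
    return Baselines(L0=low_fit, L1=high_fit,
                     r_squared_low=r2_low, r_squared_high=r2_high)


def folded_fraction(curve: MeltingCurve, baselines: Baselines) -> FoldedFractionCurve:
    """theta(T) = (L0(T) - A(T)) / (L0(T) - L1(T)); noise may push values
    slightly outside [0, 1] and is preserved, not clipped."""
    T = curve.temperature_C
    A = curve.drift_corrected()
    l0 = baselines.l0_at(T)
    l1 = baselines.l1_at(T)
    denom = l0 - l1
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("baselines intersect within the data range")
    theta = (l0 - A) / denom
    return FoldedFractionCurve(
        temperature_C=T, theta=theta, baselines=baselines, direction=curve.direction
    )


def melting_temperature(ffc: FoldedFractionCurve) -> MeltingResult:
    """Linear interpolation at the first theta = 0.5 crossing in ramp order.

    Multiple crossings (biphasic melts) trigger a multimodality warning and
    report the first crossing only; no crossing yields an undetermined
    result carrying the observed theta range.
    """
    T, th = ffc.temperature_C, ffc.theta
    rng = (float(th.min()), float(th.max()))
    s = th - 0.5
    cross = np.nonzero(s[:-1] * s[1:] <= 0)[0]
    cross = [i for i in cross if s[i] != s[i + 1] or s[i] == 0]
    if not cross:
        return MeltingResult(t_m=None, theta_range=rng)
    # biphasic detector: more than one extremum in dtheta/dT
    dth = np.gradient(th, T)
    sign_changes = int(np.count_nonzero(np.diff(np.sign(np.diff(dth))) != 0))
    multimodal = len(cross) > 1
    if multimodal:
        warnings.warn("multiple theta=0.5 crossings; reporting the first only")
    i = cross[0]
    if s[i] == 0:
        tm = float(T[i])
    else:
        tm = float(T[i] + (0.5 - th[i]) * (T[i + 1] - T[i]) / (th[i + 1] - th[i]))
    return MeltingResult(t_m=tm, theta_range=rng, multimodal=multimodal)


def hysteresis(heating: MeltingResult, cooling: MeltingResult) -> Optional[float]:
    """|T_m(heating) - T_m(cooling)|; undetermined if either is."""
    if not heating.defined or not cooling.defined:
        return None
    return abs(heating.t_m - cooling.t_m)


def delta_tm(
    with_ligand: MeltingResult, without: MeltingResult
) -> Optional[float]:
    """Signed ligand-induced melting-temperature shift (degC)."""
    if not with_ligand.defined or not without.defined:
        return None
    return with_ligand.t_m - without.t_m
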