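"""Titration analysis: noise-corrected intensities at several ligand
concentrations are fit to the sequential-binding model with free response
factors, replacing the dynamic-fitting step usually delegated to external
software.

The three-step procedure is (1) noise correction (done upstream when the
species tables are built), (2) response analysis against the dT6 internal
standard — the DNA/standard intensity ratio is regressed against ligand
concentration and each point renormalized to the zero-ligand ratio — and
(3) weighted least squares of the forward equilibrium model on normalized
species intensities, with KD1, KD2 and the relative response factors of the
complexes (r_M fixed at 1) as free parameters in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .equilibria import (
    BindingSample,
    Censored,
    concentrations_from_intensities,
    free_ligand,
    kd_single_point,
    solve_equilibrium,
)
from .spectra import SpeciesTable

LOG10_KD_BOUNDS = (-4.0, 4.0)  # micromolar
LOG10_R_BOUNDS = (-2.0, 2.0)


@dataclass
class TitrationPoint:
    L0: float
    table: SpeciesTable


@dataclass
class TitrationSeries:
    points: list[TitrationPoint]
    M0: float
    standard_conc: float = 4.0

    def __post_init__(self):
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")
        l0s = [p.L0 for p in self.points]
        if len(set(l0s)) != len(l0s) or any(x < 0 for x in l0s):
            raise ValueError("L0 values must be distinct and non-negative")
        if len(self.points) < 3:
            raise ValueError("at least 3 titration points required")


@dataclass
class DriftAnalysis:
    drift: float  # relative slope of the DNA/standard ratio per unit L0
    correction_factors: dict[float, float]  # L0 -> multiplicative correction
    intercept: float
    slope: float


@dataclass
class TitrationFit:
    KD1: Union[float, Censored]
    KD2: Union[float, Censored]
    KD1_stderr: Optional[float]
    KD2_stderr: Optional[float]
    r_ML: float
    r_ML2: float
    drift: float
    residual_norm: float
    converged: bool
    n_points: int = 0


def response_drift(series: TitrationSeries) -> DriftAnalysis:
    """Regress the total-DNA / internal-standard intensity ratio against L0.

    The fitted line quantifies how ligand addition changes DNA response
    (e.g. through spray suppression); each point's correction factor maps
    its ratio back onto the zero-ligand value. Points with zero standard
    intensity are excluded with a warning.
    """
    l0s, ratios = [], []
    for p in series.points:
        std = p.table.internal_standard_intensity
        if std <= 0:
            warnings.warn(f"point L0={p.L0}: zero standard intensity, excluded")
            continue
        total = sum(p.table.intensity_triplet())
        l0s.append(p.L0)
        ratios.append(total / std)
    if len(l0s) < 2:
        raise ValueError("need >= 2 points with positive standard intensity")
    slope, intercept = np.polyfit(l0s, ratios, 1)
    if intercept <= 0:
        raise ValueError("non-positive fitted ratio at L0=0")
    factors = {
        p.L0: intercept / (intercept + slope * p.L0) for p in series.points
    }
    return DriftAnalysis(
        drift=slope / intercept,
        correction_factors=factors,
        intercept=float(intercept),
        slope=float(slope),
    )


def model_intensities(
    sample: BindingSample, KD1: float, KD2: float, r_ML: float = 1.0,
    r_ML2: float = 1.0,
) -> tuple[float, float, float]:
    """Predicted (I_M, I_ML, I_ML2) up to a shared scale: equilibrium
    concentrations weighted by per-species response factors (r_M = 1)."""
    if min(r_ML, r_ML2) < 0:
        raise ValueError("response factors must be non-negative")
    st = solve_equilibrium(sample, KD1, KD2)
    return st.free_M, r_ML * st.ML, r_ML2 * st.ML2


def _initial_guess(series: TitrationSeries) -> np.ndarray:
    """KD estimates from the single-point equations at the mid-titration
    point; response factors start at 1."""
    pts = sorted(series.points, key=lambda p: p.L0)
    mid = pts[len(pts) // 2]
    kd1, kd2 = 1.0, 10.0
    conc = concentrations_from_intensities(
        mid.table, BindingSample(M0=series.M0, L0=mid.L0)
    )
    if conc is not None:
        M, ML, ML2 = conc
        L = free_ligand(BindingSample(M0=series.M0, L0=mid.L0), ML, ML2)
        res = kd_single_point(M, ML, ML2, L)
        if isinstance(res.KD1, (int, float)):
            kd1 = res.KD1
        if isinstance(res.KD2, (int, float)):
            kd2 = res.KD2
    clip = lambda v, b: np.clip(np.log10(v), b[0] + 0.01, b[1] - 0.01)
    return np.array(
        [clip(kd1, LOG10_KD_BOUNDS), clip(kd2, LOG10_KD_BOUNDS), 0.0, 0.0]
    )


def fit_titration(
    series: TitrationSeries,
    init: Optional[Sequence[float]] = None,
    drift_model: str = "linear",
    apply_drift_correction: bool = True,
) -> TitrationFit:
    """Weighted least squares of the sequential-binding model on normalized
    species intensities across the titration.

    Residuals compare observed and predicted per-point species fractions
    (removing the unknown spray-efficiency scale); weights are Poisson-like
    (sigma proportional to sqrt(I)) with a floor at three times the noise
    sigma. A series with no detectable complex at any point is censored.
    """
    drift_coeff = 0.0
    factors = {p.L0: 1.0 for p in series.points}
    if apply_drift_correction and drift_model != "none":
        try:
            da = response_drift(series)
            drift_coeff = da.drift if drift_model == "linear" else 0.0
            if drift_model == "linear":
                factors = da.correction_factors
        except ValueError:
            warnings.warn("drift analysis unavailable; proceeding uncorrected")

    l0s, obs, sig = [], [], []
    any_complex = False
    floor_ref = 0.0
    for p in series.points:
        trip = np.asarray(p.table.intensity_triplet(), dtype=float)
        trip = trip * factors[p.L0]
        total = trip.sum()
        if total <= 0:
            continue
        floor_ref = max(floor_ref, total)
        if trip[1] + trip[2] > 0:
            any_complex = True
        l0s.append(p.L0)
        obs.append(trip / total)
        noise_floor = max(3.0 * p.table.noise_sigma, 1e-9)
        sig.append(np.sqrt(np.maximum(trip, noise_floor)) / total)
    if not l0s:
        raise ValueError("no titration point has positive total intensity")
    if not any_complex:
        bound = series.M0 * max(l0 for l0 in l0s)
        return TitrationFit(
            KD1=Censored(bound, "above"), KD2=Censored(bound, "above"),
            KD1_stderr=None, KD2_stderr=None, r_ML=1.0, r_ML2=1.0,
            drift=drift_coeff, residual_norm=0.0, converged=False,
            n_points=len(l0s),
        )
    obs_arr = np.asarray(obs)
    sig_arr = np.asarray(sig)
    # guard against vanishing sigma on noise-free synthetic data
    sig_arr = np.maximum(sig_arr, 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd1, kd2, r_ml, r_ml2 = 10.0 ** theta
        out = np.empty_like(obs_arr)
        for i, l0 in enumerate(l0s):
            pred = np.asarray(
                model_intensities(
                    BindingSample(M0=series.M0, L0=l0), kd1, kd2, r_ml, r_ml2
                )
            )
            out[i] = obs_arr[i] - pred / pred.sum()
        return (out / sig_arr).ravel()

    x0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(series)
    lb = [LOG10_KD_BOUNDS[0]] * 2 + [LOG10_R_BOUNDS[0]] * 2
    ub = [LOG10_KD_BOUNDS[1]] * 2 + [LOG10_R_BOUNDS[1]] * 2
    sol = least_squares(
        residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=2000,
    )
    kd1, kd2, r_ml, r_ml2 = 10.0 ** sol.x

    # standard errors from the local quadratic approximation
    se = [None, None]
    dof = sol.fun.size - sol.x.size
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * 2.0 * sol.cost / dof
            sd_log = np.sqrt(np.clip(np.diag(cov), 0, None))
            ln10 = np.log(10.0)
            se = [kd1 * sd_log[0] * ln10, kd2 * sd_log[1] * ln10]
        except np.linalg.LinAlgError:
            pass

    return TitrationFit(
        KD1=float(kd1), KD2=float(kd2),
        KD1_stderr=se[0], KD2_stderr=se[1],
        r_ML=float(r_ml), r_ML2=float(r_ml2),
        drift=drift_coeff,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_points=len(l0s),
    )
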