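"""Seeded generators emulating the instrument outputs every analysis stage
consumes: native mass spectra with K+ adduct ladders, titration series on
the experimental concentration grid, stepped-field drift records, two-state
melting curves, and CD topology signatures.

Every generator returns a ground-truth ledger alongside its output so the
analysis stages can be tested for recovery, and is bit-reproducible for a
fixed seed. Defaults state the experimental world: 10 uM DNA titrated at
0/5/10/15/20/30/40 uM ligand with 4 uM dT6 internal standard; free DNA
carrying 1 specific K+ (2-quartet antiparallel) and complexes 2 (3-quartet
parallel); a 78.1 cm drift tube around 3.95 Torr helium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import poisson

from .equilibria import BindingSample, solve_equilibrium
from .masses import Ligand, Oligo, SpeciesKey, species_mz
from .mobility import (
    DRIFT_TUBE_LENGTH_CM,
    DriftRecord,
    invert_mason_schamp,
    reduced_inverse_voltage,
)
from .optical import Baselines, CDSpectrum, MeltingCurve
from .spectra import MassSpectrum, SpeciesTable
from .titration import TitrationPoint, TitrationSeries

R_GAS = 8.31446261815324e-3  # kJ mol^-1 K^-1

TITRATION_GRID_UM = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
SCREEN_M0_UM = 10.0
SCREEN_L0_UM = 20.0
STANDARD_CONC_UM = 4.0


@dataclass
class SimConfig:
    seed: int = 0
    peak_sigma: float = 0.4  # Th, Gaussian peak width of unresolved envelopes
    noise_sigma: float = 0.0  # additive baseline noise, intensity units
    response: tuple[float, float, float] = (1.0, 1.0, 1.0)  # r_M, r_ML, r_ML2
    adduct_lambda: float = 0.5  # Poisson mean of nonspecific K+ adducts
    specific_k: dict[int, int] = field(
        default_factory=lambda: {0: 1, 1: 2, 2: 2}
    )  # stoichiometry -> specific K+ count
    n_max_adducts: int = 6
    charge_states: tuple[int, ...] = (5, 4)
    titration_grid: tuple[float, ...] = TITRATION_GRID_UM
    titration_noise: float = 0.0  # multiplicative log-normal sigma
    response_drift: float = 0.0  # relative DNA-response slope per uM ligand
    intensity_scale: float = 1e4
    arrival_sigma_ms: float = 0.15
    arrival_jitter: float = 0.0  # relative jitter on apex times
    melting_noise: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def adduct_ladder_weights(cfg: SimConfig, stoichiometry: int) -> np.ndarray:
    """Channel weights over n = 0..n_max: the specific K+ count shifts a
    Poisson(nonspecific) distribution; weights renormalized on the ladder."""
    shift = cfg.specific_k.get(stoichiometry, 0)
    n = np.arange(cfg.n_max_adducts + 1)
    w = np.where(n >= shift, poisson.pmf(n - shift, max(cfg.adduct_lambda, 1e-12)), 0.0)
    if cfg.adduct_lambda == 0:
        w = (n == shift).astype(float)
    total = w.sum()
    return w / total if total > 0 else w


def speciation_intensities(
    sample: BindingSample, KD1: float, KD2: float, cfg: SimConfig
) -> tuple[float, float, float]:
    st = solve_equilibrium(sample, KD1, KD2)
    r = cfg.response
    return (
        cfg.intensity_scale * r[0] * st.free_M,
        cfg.intensity_scale * r[1] * st.ML,
        cfg.intensity_scale * r[2] * st.ML2,
    )


def simulate_spectrum(
    sample: BindingSample,
    KD1: float,
    KD2: float,
    cfg: SimConfig,
    oligo: Oligo,
    ligand: Ligand,
    mz_step: float = 0.05,
    mz_pad: float = 15.0,
) -> tuple[MassSpectrum, dict]:
    """Synthetic profile spectrum of the M/ML/ML2 adduct ladders.

    Per stoichiometry the total intensity (response-weighted concentration)
    splits over the K+ ladder, each channel becoming a Gaussian peak at its
    species m/z; additive Gaussian noise on top. The ledger records the true
    area of every species peak and flags collisions closer than 3 sigma.
    """
    totals = speciation_intensities(sample, KD1, KD2, cfg)
    peaks: list[tuple[SpeciesKey, float, float]] = []  # key, center, area
    for stoich, total in enumerate(totals):
        if total <= 0:
            continue
        weights = adduct_ladder_weights(cfg, stoich)
        for z in cfg.charge_states:
            for n, w in enumerate(weights):
                if w <= 0:
                    continue
                key = SpeciesKey(
                    target=oligo, ligand_count=stoich, k_count=n,
                    charge_magnitude=z,
                )
                center = species_mz(key, ligand)
                peaks.append((key, center, total * w / len(cfg.charge_states)))
    if not peaks:
        raise ValueError("nothing to simulate: all species at zero intensity")
    centers = np.array([c for _, c, _ in peaks])
    collisions = []
    order = np.argsort(centers)
    for a, b in zip(order[:-1], order[1:]):
        ka, kb = peaks[a][0], peaks[b][0]
        if (
            ka.ligand_count != kb.ligand_count
            and abs(centers[a] - centers[b]) < 3.0 * cfg.peak_sigma
        ):
            collisions.append((ka, kb))
    mz = np.arange(centers.min() - mz_pad, centers.max() + mz_pad, mz_step)
    intensity = np.zeros_like(mz)
    s = cfg.peak_sigma
    for _, center, area in peaks:
        intensity += (
            area / (s * np.sqrt(2.0 * np.pi))
        ) * np.exp(-0.5 * ((mz - center) / s) ** 2)
    if cfg.noise_sigma > 0:
        intensity = intensity + cfg.rng().normal(0.0, cfg.noise_sigma, mz.size)
        intensity = np.clip(intensity, 0.0, None)
    ledger = {
        "areas": {key: area for key, _, area in peaks},
        "centers": {key: center for key, center, _ in peaks},
        "stoichiometry_totals": {i: t for i, t in enumerate(totals)},
        "collisions": collisions,
        "state": solve_equilibrium(sample, KD1, KD2),
    }
    return MassSpectrum(mz=mz, intensity=intensity, sample_id="synthetic"), ledger


def _species_table_for_point(
    sample: BindingSample, KD1: float, KD2: float, cfg: SimConfig,
    oligo: Oligo, rng: np.random.Generator, drift_factor: float,
    standard_intensity: float,
) -> SpeciesTable:
    totals = speciation_intensities(sample, KD1, KD2, cfg)
    table = SpeciesTable(internal_standard_intensity=standard_intensity)
    for stoich, total in enumerate(totals):
        weights = adduct_ladder_weights(cfg, stoich)
        for z in cfg.charge_states:
            for n, w in enumerate(weights):
                val = total * w * drift_factor / len(cfg.charge_states)
                if cfg.titration_noise > 0 and val > 0:
                    val *= rng.lognormal(0.0, cfg.titration_noise)
                key = SpeciesKey(
                    target=oligo, ligand_count=stoich, k_count=n,
                    charge_magnitude=z,
                )
                table.entries[key] = val
    return table


def simulate_titration(
    M0: float,
    grid: Sequence[float],
    KD1: float,
    KD2: float,
    cfg: SimConfig,
    oligo: Optional[Oligo] = None,
) -> tuple[TitrationSeries, dict]:
    """A SpeciesTable per grid point from the forward equilibrium model,
    with optional multiplicative noise and injected linear response drift."""
    oligo = oligo or Oligo("synthetic", "TGGGT")
    rng = cfg.rng()
    points = []
    for l0 in grid:
        sample = BindingSample(M0=M0, L0=l0, standard_conc=STANDARD_CONC_UM)
        drift_factor = 1.0 + cfg.response_drift * l0
        std = cfg.intensity_scale * STANDARD_CONC_UM / 10.0
        table = _species_table_for_point(
            sample, KD1, KD2, cfg, oligo, rng, drift_factor, std
        )
        points.append(TitrationPoint(L0=float(l0), table=table))
    series = TitrationSeries(points=points, M0=M0, standard_conc=STANDARD_CONC_UM)
    ledger = {
        "KD1": KD1, "KD2": KD2, "response": cfg.response,
        "response_drift": cfg.response_drift,
        "states": {
            float(l0): solve_equilibrium(BindingSample(M0=M0, L0=l0), KD1, KD2)
            for l0 in grid
        },
    }
    return series, ledger


def simulate_drift(
    ccs_true: float | Sequence[float],
    z: int,
    ion_mass: float,
    voltages: Sequence[float],
    pressure_torr: float = 3.95,
    temperature_K: float = 296.0,
    cfg: Optional[SimConfig] = None,
    t0_ms: float = 0.3,
    length_cm: float = DRIFT_TUBE_LENGTH_CM,
    weights: Optional[Sequence[float]] = None,
) -> tuple[list[DriftRecord], dict]:
    """Gaussian arrival-time peaks at the stepped-field prediction for one
    or several CCS populations; optional seeded apex jitter."""
    cfg = cfg or SimConfig()
    if len(voltages) < 2:
        raise ValueError("need >= 2 drift voltages")
    ccs_list = np.atleast_1d(np.asarray(ccs_true, dtype=float))
    w = np.ones(ccs_list.size) if weights is None else np.asarray(weights, float)
    k0s = np.array(
        [invert_mason_schamp(c, z, ion_mass, temperature_K) for c in ccs_list]
    )
    rng = cfg.rng()
    records = []
    true_centers = {}
    for dv in voltages:
        probe = DriftRecord(
            arrival_ms=np.array([0.0, 1.0]), intensity=np.array([0.0, 0.0]),
            delta_V=dv, pressure_torr=pressure_torr, temperature_K=temperature_K,
        )
        x = reduced_inverse_voltage(probe, length_cm)
        centers = t0_ms + (x / k0s) * 1e3
        if cfg.arrival_jitter > 0:
            centers = centers * (1.0 + rng.normal(0.0, cfg.arrival_jitter, centers.size))
        true_centers[float(dv)] = centers.copy()
        lo = max(centers.min() - 8.0 * cfg.arrival_sigma_ms, 1e-3)
        hi = centers.max() + 8.0 * cfg.arrival_sigma_ms
        t = np.linspace(lo, hi, 600)
        y = np.zeros_like(t)
        for c, wi in zip(centers, w):
            y += wi * np.exp(-0.5 * ((t - c) / cfg.arrival_sigma_ms) ** 2)
        records.append(
            DriftRecord(
                arrival_ms=t, intensity=y, delta_V=float(dv),
                pressure_torr=pressure_torr, temperature_K=temperature_K,
            )
        )
    ledger = {
        "ccs": ccs_list, "K0": k0s, "t0_ms": t0_ms,
        "apex_centers_ms": true_centers,
    }
    return records, ledger


def simulate_melting(
    t_m_C: float = 55.0,
    enthalpy_kJ: float = 200.0,
    baselines: Optional[Baselines] = None,
    direction: str = "heating",
    cfg: Optional[SimConfig] = None,
    t_range_C: tuple[float, float] = (4.0, 90.0),
    n_points: int = 173,
    wavelength_nm: int = 295,
) -> tuple[MeltingCurve, dict]:
    """Two-state van't Hoff melting curve.

    The unfolding constant is K_u(T) = exp(-dH/R (1/T - 1/Tm)) (dH > 0,
    dS = dH/Tm), giving a folded fraction theta = 1/(1+K_u) that is exactly
    0.5 at Tm. Absorbance mixes the two affine baselines by theta.
    """
    cfg = cfg or SimConfig()
    if baselines is None:
        # 295 nm convention: folded (low-T) absorbs higher
        baselines = Baselines(L0=(0.30, 0.0004), L1=(0.55, -0.0003))
    if not (t_range_C[0] < t_m_C < t_range_C[1]):
        raise ValueError("t_m must lie inside the scan range")
    T = np.linspace(t_range_C[0], t_range_C[1], n_points)
    if direction == "cooling":
        T = T[::-1]
    TK = T + 273.15
    tmK = t_m_C + 273.15
    ku = np.exp(-enthalpy_kJ / R_GAS * (1.0 / TK - 1.0 / tmK))
    theta = 1.0 / (1.0 + ku)
    A = baselines.l0_at(T) * (1.0 - theta) + baselines.l1_at(T) * theta
    if cfg.melting_noise > 0:
        A = A + cfg.rng().normal(0.0, cfg.melting_noise, A.size)
    curve = MeltingCurve(
        temperature_C=T, absorbance=A, wavelength_nm=wavelength_nm,
        direction=direction,
    )
    ledger = {"t_m": t_m_C, "enthalpy_kJ": enthalpy_kJ, "theta": theta,
              "baselines": baselines}
    return curve, ledger


# CD band fixtures (positions nm, widths nm, amplitudes in Delta-eps units).
# These are plausible topology signatures for testing, not measured science.
CD_BANDS = {
    "parallel": [(264.0, 12.0, 220.0), (245.0, 9.0, -80.0)],
    "antiparallel": [(295.0, 12.0, 120.0), (265.0, 11.0, -60.0)],
    "hybrid": [(290.0, 13.0, 90.0), (268.0, 12.0, 110.0), (240.0, 9.0, -50.0)],
}


def simulate_cd(
    topology: str,
    c_molar: float = 10e-6,
    path_cm: float = 0.2,
    cfg: Optional[SimConfig] = None,
    wl_range: tuple[float, float] = (220.0, 340.0),
    n_points: int = 601,
) -> tuple[CDSpectrum, dict]:
    """Synthetic CD spectrum: fixed Gaussian bands per topology, scaled from
    molar ellipticity to mdeg through the inverse of the conversion law."""
    from .constants import CD_CONVERSION

    cfg = cfg or SimConfig()
    if topology not in CD_BANDS:
        raise ValueError(f"unknown topology {topology!r}")
    wl = np.linspace(wl_range[0], wl_range[1], n_points)
    d_eps = np.zeros_like(wl)
    for center, width, amp in CD_BANDS[topology]:
        d_eps += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    mdeg = d_eps * CD_CONVERSION * c_molar * path_cm
    if cfg.noise_sigma > 0:
        mdeg = mdeg + cfg.rng().normal(0.0, cfg.noise_sigma, mdeg.size)
    spec = CDSpectrum(
        wavelength_nm=wl, ellipticity_mdeg=mdeg, c_molar=c_molar, path_cm=path_cm
    )
    ledger = {"topology": topology, "delta_eps": d_eps, "bands": CD_BANDS[topology]}
    return spec, ledger
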