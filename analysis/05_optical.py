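"""Optical demo: melting-temperature shift on ligand binding and CD
topology signatures. Simulates two-state UV-melting curves without and with
a stabilizing ligand (+8.2 degC shift, the kind of stabilization seen for a
tight 1:1 complex), extracts Tm from both ramps, and converts synthetic CD
spectra of the three canonical G4 topologies to molar ellipticity."""

import json
from pathlib import Path

import numpy as np

from g4screen.optical import (
    delta_tm,
    fit_baselines,
    folded_fraction,
    hysteresis,
    melting_temperature,
    molar_ellipticity,
)
from g4screen.synthetic import SimConfig, simulate_cd, simulate_melting

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _tm(t_m, direction="heating"):
    curve, _ = simulate_melting(
        t_m_C=t_m, enthalpy_kJ=250.0, direction=direction,
        cfg=SimConfig(seed=2, melting_noise=0.002),
    )
    return melting_temperature(folded_fraction(curve, fit_baselines(curve)))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    free = _tm(48.0)
    bound = _tm(56.2)
    free_cool = _tm(48.0, "cooling")
    shift = delta_tm(bound, free)
    hyst = hysteresis(free, free_cool)
    print(f"Tm(free) = {free.t_m:.2f} C, Tm(+ligand) = {bound.t_m:.2f} C, "
          f"delta Tm = {shift:+.2f} C, hysteresis = {hyst:.2f} C")
    report = {"t_m_free": free.t_m, "t_m_bound": bound.t_m,
              "delta_t_m": shift, "hysteresis": hyst}
    (RESULTS / "melting.json").write_text(json.dumps(report, indent=2))

    with open(RESULTS / "cd_signatures.csv", "w") as fh:
        fh.write("topology,wavelength_nm,delta_eps\n")
        for topo in ("parallel", "antiparallel", "hybrid"):
            spec, _ = simulate_cd(topo)
            d_eps = molar_ellipticity(spec)
            i = int(np.argmax(np.abs(d_eps)))
            print(f"CD {topo}: dominant band {d_eps[i]:+.1f} M^-1 cm^-1 "
                  f"at {spec.wavelength_nm[i]:.0f} nm")
            for wl, de in zip(spec.wavelength_nm[::10], d_eps[::10]):
                fh.write(f"{topo},{wl:.1f},{de:.4f}\n")
    print(f"wrote {RESULTS / 'melting.json'} and cd_signatures.csv")


if __name__ == "__main__":
    main()
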