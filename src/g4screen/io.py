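"""Plain-text serialization: species tables, drift records, melting and CD
curves, sample sheets. All formats are small CSVs so runs are reproducible
and diffable."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .masses import Ligand, Oligo, SpeciesKey
from .mobility import DriftRecord
from .optical import CDSpectrum, MeltingCurve
from .spectra import SpeciesTable


def write_species_table(path, table: SpeciesTable) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# noise_sigma={float(table.noise_sigma)!r}\n")
        fh.write(
            f"# internal_standard_intensity={float(table.internal_standard_intensity)!r}\n"
        )
        w = csv.writer(fh)
        w.writerow(["ligand_count", "k_count", "nh4_count", "z", "intensity"])
        for key, val in sorted(
            table.entries.items(),
            key=lambda kv: (kv[0].ligand_count, kv[0].k_count,
                            kv[0].nh4_count, kv[0].charge_magnitude),
        ):
            w.writerow(
                [key.ligand_count, key.k_count, key.nh4_count,
                 key.charge_magnitude, repr(float(val))]
            )


def read_species_table(path, target: Optional[Oligo] = None) -> SpeciesTable:
    target = target or Oligo("unknown", "T")
    noise_sigma = 0.0
    standard = 0.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                k = k.strip()
                if k == "noise_sigma":
                    noise_sigma = float(v)
                elif k == "internal_standard_intensity":
                    standard = float(v)
                continue
            rows.append(line)
    reader = csv.DictReader(rows)
    table = SpeciesTable(
        noise_sigma=noise_sigma, internal_standard_intensity=standard
    )
    for rec in reader:
        key = SpeciesKey(
            target=target,
            ligand_count=int(rec["ligand_count"]),
            k_count=int(rec["k_count"]),
            nh4_count=int(rec["nh4_count"]),
            charge_magnitude=int(rec["z"]),
        )
        table.entries[key] = float(rec["intensity"])
    return table


def write_drift_record(path, record: DriftRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f"# delta_V={float(record.delta_V)!r}\n")
        fh.write(f"# pressure_torr={float(record.pressure_torr)!r}\n")
        fh.write(f"# temperature_K={float(record.temperature_K)!r}\n")
        fh.write("time_ms,intensity\n")
        for t, y in zip(record.arrival_ms, record.intensity):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_drift_record(path) -> DriftRecord:
    meta = {}
    times, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = float(v)
                continue
            if line.startswith("time_ms"):
                continue
            t, _, y = line.partition(",")
            times.append(float(t))
            inten.append(float(y))
    return DriftRecord(
        arrival_ms=np.asarray(times), intensity=np.asarray(inten),
        delta_V=meta["delta_V"], pressure_torr=meta["pressure_torr"],
        temperature_K=meta["temperature_K"],
    )


def write_melting_curve(path, curve: MeltingCurve) -> None:
    df = pd.DataFrame(
        {
            "temperature_C": curve.temperature_C,
            "absorbance": curve.absorbance,
            "wavelength_nm": curve.wavelength_nm,
            "direction": curve.direction,
        }
    )
    df.to_csv(path, index=False)


def read_melting_curve(path) -> MeltingCurve:
    df = pd.read_csv(path)
    return MeltingCurve(
        temperature_C=df["temperature_C"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        wavelength_nm=int(df["wavelength_nm"].iloc[0]),
        direction=str(df["direction"].iloc[0]),
    )


def write_cd_spectrum(path, spec: CDSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# c_molar={float(spec.c_molar)!r}\n")
        fh.write(f"# path_cm={float(spec.path_cm)!r}\n")
        fh.write("wavelength_nm,ellipticity_mdeg\n")
        for wl, th in zip(spec.wavelength_nm, spec.ellipticity_mdeg):
            fh.write(f"{float(wl)!r},{float(th)!r}\n")


def read_cd_spectrum(path) -> CDSpectrum:
    meta = {"c_molar": 1e-5, "path_cm": 1.0}
    wl, th = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("wavelength"):
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = float(v)
                continue
            a, _, b = line.partition(",")
            wl.append(float(a))
            th.append(float(b))
    return CDSpectrum(
        wavelength_nm=np.asarray(wl), ellipticity_mdeg=np.asarray(th),
        c_molar=meta["c_molar"], path_cm=meta["path_cm"],
    )


def read_sample_sheet(path) -> list[dict]:
    """Sample sheet CSV: name, sequence, strand_count, ligand_name, ligand_mass."""
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            oligo = Oligo(
                name=rec["name"], sequence=rec["sequence"].upper(),
                strand_count=int(rec.get("strand_count") or 1),
            )
            ligand = None
            if rec.get("ligand_name"):
                ligand = Ligand(
                    name=rec["ligand_name"], neutral_mass=float(rec["ligand_mass"])
                )
            out.append({"oligo": oligo, "ligand": ligand, "raw": rec})
    return out
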