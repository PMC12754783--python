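"""Physical-constant registry shared by every module.

All mass bookkeeping is in daltons, m/z in thomson, mobilities in
cm^2 V^-1 s^-1, cross sections in square angstroms. Values live here so a
single edit propagates everywhere (e.g. the standard-conditions convention
for the Loschmidt number).
"""

# Cation-adduct mass shifts in negative mode: the cation replaces a proton,
# so the shift is M(cation) - M(H).
PROTON_MASS = 1.007276  # Da, mass of H+
DELTA_K = 37.9559  # Da, K replaces H
DELTA_NH4 = 17.0265  # Da, NH4 replaces H (net +NH3)

HELIUM_MASS = 4.0026  # Da, drift gas

# Loschmidt convention for the gas number density reference state.
T0_K = 273.15  # K
P0_TORR = 760.0  # Torr (1 atm)
N0_LOSCHMIDT = 2.686780111e25  # m^-3 at (T0_K, P0_TORR)

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
DA_TO_KG = 1.66053906660e-27

# CD conversion denominator: ellipticity (mdeg) -> molar ellipticity
# Delta-epsilon (M^-1 cm^-1) via theta / (CD_CONVERSION * c * l).
CD_CONVERSION = 32980.0

# Average and monoisotopic atomic masses used for oligonucleotide arithmetic.
ATOMIC_MASS_AVERAGE = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
}
ATOMIC_MASS_MONO = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}
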