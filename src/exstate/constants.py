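"""Physical constants and coupling-type definitions.

All residual dipolar couplings are expressed on the amide N-H scale: the
Saupe tensor is fitted in Hz-on-NH-scale units, and each coupling type
enters through its dipolar interaction constant relative to N-H, computed
from gyromagnetic ratios and effective bond lengths.
"""

from __future__ import annotations

import numpy as np

#: Gyromagnetic ratios, rad s^-1 T^-1.
GAMMA = {
    "1H": 267.522e6,
    "13C": 67.2828e6,
    "15N": -27.1266e6,
    "31P": 108.394e6,
}

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Effective internuclear distances (Angstrom) used for dipolar constants.
#: These are vibrationally corrected effective lengths, not equilibrium ones.
EFFECTIVE_BOND_LENGTH = {
    "NH": 1.041,
    "CAHA": 1.117,
    "NC": 1.329,
    "HNC": 2.085,
}

#: Nuclei of each coupling type (determines the gamma product).
COUPLING_NUCLEI = {
    "NH": ("15N", "1H"),
    "CAHA": ("13C", "1H"),
    "NC": ("15N", "13C"),
    "HNC": ("1H", "13C"),
}

#: (atom_a, atom_b, residue offset of atom_b) defining each bond vector.
#: NC is the one-bond N(i)-C'(i-1) coupling; HNC the two-bond HN(i)-C'(i-1).
COUPLING_ATOMS = {
    "NH": ("N", "H", 0),
    "CAHA": ("CA", "HA", 0),
    "NC": ("N", "C", -1),
    "HNC": ("H", "C", -1),
}

COUPLING_TYPES = tuple(COUPLING_ATOMS)

#: Accepted spellings for coupling types in input tables.
COUPLING_ALIASES = {
    "NH": "NH", "N-H": "NH", "DNH": "NH", "1DNH": "NH", "N_H": "NH",
    "CAHA": "CAHA", "CA-HA": "CAHA", "CAH": "CAHA", "1DCAHA": "CAHA",
    "CA_HA": "CAHA", "C-H": "CAHA",
    "NC": "NC", "N-C": "NC", "NC'": "NC", "N-C'": "NC", "1DNC": "NC",
    "HNC": "HNC", "HN-C": "HNC", "HNC'": "HNC", "HN-C'": "HNC", "2DHNC": "HNC",
}


def dmax_ratio(coupling_type: str) -> float:
    """Dipolar constant of `coupling_type` relative to N-H.

    D_max is proportional to gamma_i * gamma_j / r^3; only the ratio to the
    N-H constant is needed when couplings are kept on the N-H scale.
    """
    g1, g2 = COUPLING_NUCLEI[coupling_type]
    gn, gh = COUPLING_NUCLEI["NH"]
    num = GAMMA[g1] * GAMMA[g2] / EFFECTIVE_BOND_LENGTH[coupling_type] ** 3
    den = GAMMA[gn] * GAMMA[gh] / EFFECTIVE_BOND_LENGTH["NH"] ** 3
    return float(num / den)


DMAX_RATIO = {t: dmax_ratio(t) for t in COUPLING_TYPES}


def larmor_frequency(nucleus: str, proton_mhz: float) -> float:
    """Larmor frequency (MHz, absolute value) of `nucleus` at a field
    specified by its 1H frequency in MHz (the spectrometer convention)."""
    return abs(GAMMA[nucleus] / GAMMA["1H"]) * proton_mhz


def ppm_to_rad_s(delta_ppm: float, nucleus: str, proton_mhz: float) -> float:
    """Convert a chemical-shift difference in ppm to rad/s."""
    return 2.0 * np.pi * larmor_frequency(nucleus, proton_mhz) * delta_ppm
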