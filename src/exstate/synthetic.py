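"""Synthetic data with known ground truth for every pipeline stage.

The default ("paperlike") truth mirrors the experimental regime of a small
GTPase G-domain studied by relaxation dispersion and RDCs: a ~166-residue
mixed alpha/beta protein exchanging between a dominant ground state and a
30%-populated excited conformer whose backbone departs by less than 3 A in
two localized segments; four backbone RDC types measured in two alignment
media with realistic per-type precision; two-site CPMG dispersion of seven
methyl probes at three temperatures with Arrhenius-coupled rates
(pB = 15% and kex = 1000 /s at 25 C, population rising toward 30% on
cooling); and temperature series of 1D exchange lineshapes that coalesce on
warming.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import DMAX_RATIO, ppm_to_rad_s
from .exchange import (ArrheniusLaw, SpectrumGrid, arrhenius_k, lineshape_1d,
                       r2eff_exact_grid, two_site_exchange_matrix)
from .formats_io import Atom, DispersionRecord, RdcRecord, StructureModel
from .rdc import AlignmentTensor, build_bond_vectors, vector_map
from .refine import (EnsembleModel, add_protons, local_geometry_pairs,
                     strip_protons)
from . import geometry

# secondary-structure plan loosely following a G-domain topology:
# (start, end, kind) in 1-based residue numbering; rest is loop
DEFAULT_SS_PLAN = [
    (3, 9, "E"), (15, 25, "H"), (38, 46, "E"), (49, 58, "E"),
    (66, 74, "H"), (77, 83, "E"), (87, 104, "H"), (111, 116, "E"),
    (127, 137, "H"), (141, 143, "E"), (148, 165, "H"),
]
PHI_PSI = {"H": (-57.0, -47.0), "E": (-120.0, 130.0), "L": (-80.0, 150.0)}

SWITCH_RANGES = [(30, 38), (59, 76)]
DEFAULT_SEGMENTS = ((105, 116), (127, 140))
PROBE_RESIDUES = (21, 24, 36, 55, 100, 139, 142)

RDC_SIGMA = {"NH": 0.5, "CAHA": 1.0, "NC": 0.2, "HNC": 0.2}
R2EFF_SIGMA = 0.2
CPMG_TEMPERATURES = (293.15, 298.15, 303.15)
NU_CPMG_GRID = (100.0, 200.0, 400.0, 500.0, 800.0, 1000.0)
NU_CPMG_REPEATS = (100.0, 400.0, 1000.0)


@dataclass
class SyntheticTruth:
    """Everything the generators know and the pipeline must recover."""

    ground: StructureModel
    minor: StructureModel
    w_minor: float
    tensors: dict                      # medium -> AlignmentTensor
    arrhenius_k1: ArrheniusLaw
    arrhenius_km1: ArrheniusLaw
    dw_ppm: dict                       # probe resnum -> ppm (13C)
    r20: dict                          # (resnum, temperature) -> s^-1
    rdc_sigma: dict = field(default_factory=lambda: dict(RDC_SIGMA))
    r2eff_sigma: float = R2EFF_SIGMA
    seed: int = 0
    displaced_segments: tuple = DEFAULT_SEGMENTS
    switch_ranges: tuple = tuple(SWITCH_RANGES)
    field_mhz: float = 700.0

    def pb_at(self, temperature: float) -> float:
        k1 = arrhenius_k(self.arrhenius_k1, temperature)
        km1 = arrhenius_k(self.arrhenius_km1, temperature)
        return k1 / (k1 + km1)

    def kex_at(self, temperature: float) -> float:
        return arrhenius_k(self.arrhenius_k1, temperature) + \
            arrhenius_k(self.arrhenius_km1, temperature)

    def ensemble(self) -> EnsembleModel:
        return EnsembleModel([self.ground, self.minor],
                             [1.0 - self.w_minor, self.w_minor])


# ---------------------------------------------------------------------------
# structures

def _build_backbone(n_residues: int, ss_plan) -> StructureModel:
    """Idealized polyalanine backbone from per-residue phi/psi."""
    kind = {}
    for a, b, k in ss_plan:
        for r in range(a, b + 1):
            kind[r] = k
    phi = {r: PHI_PSI[kind.get(r, "L")][0] for r in range(1, n_residues + 1)}
    psi = {r: PHI_PSI[kind.get(r, "L")][1] for r in range(1, n_residues + 1)}

    atoms: list[Atom] = []

    def add(r, name, element, pos):
        atoms.append(Atom("A", r, "ALA", name, element, np.asarray(pos, float)))

    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([geometry.BOND[("N", "CA")], 0.0, 0.0])
    ang = np.deg2rad(geometry.ANGLE[("N", "CA", "C")])
    c = ca + geometry.BOND[("CA", "C")] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for r in range(1, n_residues + 1):
        add(r, "N", "N", n)
        add(r, "CA", "C", ca)
        add(r, "C", "C", c)
        o = geometry.place_atom(n, ca, c, geometry.BOND[("C", "O")],
                                geometry.ANGLE[("CA", "C", "O")],
                                psi[r] + 180.0)
        add(r, "O", "O", o)
        cb = geometry.build_cb(ca, n, c)
        add(r, "CB", "C", cb)
        if r < n_residues:
            n_next = geometry.place_atom(n, ca, c, geometry.BOND[("C", "N")],
                                         geometry.ANGLE[("CA", "C", "N")],
                                         psi[r])
            ca_next = geometry.place_atom(ca, c, n_next,
                                          geometry.BOND[("N", "CA")],
                                          geometry.ANGLE[("C", "N", "CA")],
                                          180.0)
            c_next = geometry.place_atom(c, n_next, ca_next,
                                         geometry.BOND[("CA", "C")],
                                         geometry.ANGLE[("N", "CA", "C")],
                                         phi[r + 1])
            n, ca, c = n_next, ca_next, c_next
    model = StructureModel(atoms, metadata=f"synthetic {n_residues}-residue backbone")
    return add_protons(model)


def _regularize(structure: StructureModel, target: np.ndarray,
                k_geom: float = 2000.0, k_target: float = 1.0) -> np.ndarray:
    """Pull coordinates toward `target` while restraining local covalent
    geometry (bonded/1-3/1-4 distances) to the input structure's values."""
    pi, pj, d0, _ = local_geometry_pairs(structure)

    def fg(x_flat):
        x = x_flat.reshape(-1, 3)
        dv = x[pi] - x[pj]
        d = np.linalg.norm(dv, axis=1)
        dd = d - d0
        e = k_geom * float(dd @ dd)
        g = np.zeros_like(x)
        coef = (2.0 * k_geom * dd / np.maximum(d, 1e-9))[:, None] * dv
        np.add.at(g, pi, coef)
        np.add.at(g, pj, -coef)
        diff = x - target
        e += k_target * float(np.sum(diff * diff))
        g += 2.0 * k_target * diff
        return e, g.ravel()

    res = minimize(fg, target.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    return res.x.reshape(-1, 3)


def make_two_state_structures(n_residues: int = 166,
                              displaced_segments=DEFAULT_SEGMENTS,
                              tilt_angle_deg: float = 22.0,
                              max_displacement: float = 3.0,
                              taper: int = 3,
                              ss_plan=DEFAULT_SS_PLAN,
                              seed: int = 0):
    """Ground structure plus a minor conformer with smooth, localized
    displacements of the requested segments.

    Each segment is tilted about a random axis through its centroid
    (rotations, unlike translations, are what RDCs sense), the rotation
    tapering off over the three residues at each end; the result is then
    geometry-regularized so both structures are chemically regular.
    """
    ground = _build_backbone(n_residues, ss_plan)
    heavy = strip_protons(ground)
    rng = np.random.default_rng(seed)
    xyz = heavy.coords()
    target = xyz.copy()
    resnums = np.array([a.resnum for a in heavy.atoms])
    moved = False
    for (a, b) in displaced_segments:
        if a < 1 or b > n_residues:
            raise ValueError(f"segment {a}-{b} outside sequence")
        if tilt_angle_deg == 0.0:
            continue
        moved = True
        sel = (resnums >= a) & (resnums <= b)
        center = xyz[sel].mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        for r in range(a, b + 1):
            frac = 1.0
            if r > b - taper:
                frac = 0.5 * (1.0 + np.cos(np.pi * (r - (b - taper)) / taper))
            elif r < a + taper:
                frac = 0.5 * (1.0 + np.cos(np.pi * (a + taper - r) / taper))
            rot = geometry.rotation_about_axis(axis, tilt_angle_deg * frac)
            rsel = sel & (resnums == r)
            target[rsel] = (xyz[rsel] - center) @ rot.T + center
    if not moved:
        return ground, ground.copy()
    new_xyz = _regularize(heavy, target)
    disp = np.linalg.norm(new_xyz - xyz, axis=1)
    if disp.max() > max_displacement:
        raise ValueError(f"displacement request gives {disp.max():.2f} A > "
                         f"cap {max_displacement} A")
    minor = add_protons(heavy.with_coords(new_xyz))
    return ground, minor


def _tensor_from(da: float, rhombicity: float,
                 rotation: np.ndarray) -> AlignmentTensor:
    szz = 2.0 * da
    sxx = -da + 1.5 * rhombicity * da
    syy = -da - 1.5 * rhombicity * da
    m = rotation @ np.diag([sxx, syy, szz]) @ rotation.T
    return AlignmentTensor(np.array([m[0, 0], m[1, 1], m[0, 1],
                                     m[0, 2], m[1, 2]]))


def make_paperlike_truth(seed: int = 0, n_residues: int = 166,
                         w_minor: float = 0.30,
                         tilt_angle_deg: float = 22.0) -> SyntheticTruth:
    """Default study conditions; see the module docstring."""
    ground, minor = make_two_state_structures(
        n_residues, tilt_angle_deg=tilt_angle_deg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    tensors = {
        "pf1": _tensor_from(10.0, 0.30, geometry.random_rotation(rng)),
        "bicelles": _tensor_from(-8.0, 0.55, geometry.random_rotation(rng)),
    }
    k1 = ArrheniusLaw.from_rate_at(150.0, 298.15, 30.0)
    km1 = ArrheniusLaw.from_rate_at(850.0, 298.15, 60.0)
    dw = {r: float(rng.uniform(0.7, 2.5)) for r in PROBE_RESIDUES}
    r20 = {(r, t): float(rng.uniform(8.0, 15.0))
           for r in PROBE_RESIDUES for t in CPMG_TEMPERATURES}
    return SyntheticTruth(ground, minor, w_minor, tensors, k1, km1, dw, r20,
                          seed=seed)


def make_one_state_truth(seed: int = 0, n_residues: int = 166) -> SyntheticTruth:
    """Null model: no excited state (minor identical to ground, weight 0),
    emulating the wild-type-shaped negative control."""
    truth = make_paperlike_truth(seed, n_residues, w_minor=0.0,
                                 tilt_angle_deg=0.0)
    return truth


# ---------------------------------------------------------------------------
# RDC sets

def _jitter(vec: np.ndarray, sigma_deg: float,
            rng: np.random.Generator) -> np.ndarray:
    if sigma_deg == 0.0:
        return vec
    axis = rng.normal(size=3)
    axis -= (axis @ vec) * vec
    axis /= np.linalg.norm(axis)
    rot = geometry.rotation_about_axis(axis, rng.normal(0.0, sigma_deg))
    return rot @ vec


def simulate_rdc_sets(truth: SyntheticTruth, media=None, types=None,
                      completeness: float = 1.0,
                      orientation_noise_deg: float = 0.0,
                      residue_subset=None, noise: bool = True,
                      seed: int | None = None) -> list[RdcRecord]:
    """Population-weighted RDC observations with Gaussian noise.

    Switch-region residues are always dropped (emulating exchange
    broadening). `completeness` randomly retains that fraction of the
    remaining residues per set; `residue_subset` restricts to an explicit
    residue list (for sparse, anisotropic sampling studies);
    `orientation_noise_deg` jitters the generating bond vectors away from
    the fitting structure's ideal vectors.
    """
    media = list(truth.tensors) if media is None else list(media)
    types = list(RDC_SIGMA) if types is None else list(types)
    rng = np.random.default_rng(truth.seed + 10 if seed is None else seed)
    switch = set()
    for a, b in truth.switch_ranges:
        switch.update(range(a, b + 1))
    conf_vms = [vector_map(build_bond_vectors(c))
                for c in (truth.ground, truth.minor)]
    weights = (1.0 - truth.w_minor, truth.w_minor)
    records = []
    for medium in media:
        tensor = truth.tensors[medium]
        for t in types:
            keys = [k for k in conf_vms[0]
                    if k[1] == t and k[0] not in switch and k in conf_vms[1]]
            keys.sort()
            for key in keys:
                if residue_subset is not None and key[0] not in residue_subset:
                    continue
                if completeness < 1.0 and rng.random() > completeness:
                    continue
                d = 0.0
                for wk, vm in zip(weights, conf_vms):
                    if wk == 0.0:
                        continue
                    bv = vm[key]
                    vec = _jitter(bv.vector, orientation_noise_deg, rng)
                    d += wk * bv.dmax * (vec @ tensor.matrix @ vec)
                sigma = truth.rdc_sigma[t]
                if noise:
                    d += rng.normal(0.0, sigma)
                records.append(RdcRecord(key[0], t, medium, float(d), sigma))
    return records


# ---------------------------------------------------------------------------
# dispersion and spectra

def simulate_dispersion(truth: SyntheticTruth,
                        temperatures=CPMG_TEMPERATURES,
                        nu_grid=NU_CPMG_GRID, repeats=NU_CPMG_REPEATS,
                        noise: bool = True,
                        seed: int | None = None) -> list[DispersionRecord]:
    """Two-site CPMG profiles of the methyl probes at several temperatures,
    rates following the truth's Arrhenius pair, shift differences fixed
    across temperature, with repeated points as acquired experimentally."""
    rng = np.random.default_rng(truth.seed + 20 if seed is None else seed)
    records = []
    nus = list(nu_grid) + list(repeats)
    for temp in temperatures:
        kex = truth.kex_at(temp)
        pb = truth.pb_at(temp)
        for resnum, dw_ppm in truth.dw_ppm.items():
            dw_rad = ppm_to_rad_s(dw_ppm, "13C", truth.field_mhz)
            g = r2eff_exact_grid(1 - pb, pb, kex, [dw_rad], np.array(nus))[0]
            r20 = truth.r20[(resnum, temp)]
            for nu, base in zip(nus, g):
                r2 = r20 + base
                if noise:
                    r2 += rng.normal(0.0, truth.r2eff_sigma)
                records.append(DispersionRecord(
                    resnum, "13C-methyl", truth.field_mhz, temp, float(nu),
                    None, None, float(r2), truth.r2eff_sigma))
    return records


def simulate_spectrum_series(truth: SyntheticTruth, resnum: int,
                             temperatures=(276.15, 283.15, 293.15, 303.15),
                             r2_intrinsic: float = 15.0,
                             n_points: int = 6000) -> list[SpectrumGrid]:
    """1D two-site exchange lineshapes of one probe across temperatures:
    split peaks in the slow-exchange cold limit, coalescence on warming."""
    dw_rad = ppm_to_rad_s(truth.dw_ppm[resnum], "13C", truth.field_mhz)
    lo = -0.8 * dw_rad - 30.0 * r2_intrinsic
    hi = 1.8 * dw_rad + 30.0 * r2_intrinsic
    grid = np.linspace(lo, hi, n_points)
    out = []
    for temp in temperatures:
        pb = truth.pb_at(temp)
        kex = truth.kex_at(temp)
        sites = [(1.0 - pb, 0.0, r2_intrinsic), (pb, dw_rad, r2_intrinsic)]
        x = two_site_exchange_matrix(1.0 - pb, pb, kex)
        out.append(lineshape_1d(sites, x, grid))
    return out
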