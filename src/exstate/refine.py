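"""Population-weighted N=2 ensemble refinement against RDCs.

The excited (minor) conformer of a two-state ensemble is refined in
Cartesian coordinates against multi-medium RDC sets while the ground-state
conformer stays fixed to the crystal structure. The objective is

    E = sum_sets k_rdc * sum ((D_obs - [(1-w) D_ground + w D_minor]) / sigma)^2
      + k_geom * sum_pairs (d_ij - d_ij^0)^2          (bonded + 1-3/1-4)
      + k_disp * sum_atoms max(0, |r_i - r_i^0| - cap)^2
      + k_dihe * sum flat-bottom dihedral restraint violations^2

minimized by bounded quasi-Newton descent from many randomly perturbed
starts; the reported ensemble is the n_keep lowest-energy runs. Alignment
tensors are fitted beforehand and held fixed throughout.

Cross-validation excludes one RDC set at a time, refines on the rest, and
scores the held-out set with the R-free quality factor; repeating this over
a grid of minor-state populations locates the optimal population ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .constants import DMAX_RATIO
from .formats_io import Atom, RdcRecord, StructureModel
from .rdc import (AlignmentTensor, back_calc_rdc, build_bond_vectors,
                  quality_factors, vector_map)
from . import geometry

log = logging.getLogger("exstate")


@dataclass
class EnsembleModel:
    """Weighted list of conformers sharing residue numbering."""

    conformers: list[StructureModel]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        nums = self.conformers[0].residue_numbers()
        for c in self.conformers[1:]:
            if c.residue_numbers() != nums:
                raise ValueError("conformers must share residue numbering")


@dataclass(frozen=True)
class DihedralRestraint:
    resnum: int
    angle: str          # "phi", "psi" or "omega"
    target_deg: float
    halfwidth_deg: float


@dataclass
class RefinementConfig:
    max_displacement: float = 3.0          # Angstrom cap on departures
    k_rdc: float = 1.0                     # global RDC weight multiplier
    rdc_weights: dict = field(default_factory=dict)  # (medium, type) -> k
    k_geom: float = 3000.0                 # elastic local-geometry weight
    k_disp: float = 200.0                  # displacement-cap weight
    k_dihe: float = 500.0                  # dihedral restraint weight (rad^-2)
    dihedral_restraints: list = field(default_factory=list)
    n_runs: int = 100
    n_keep: int = 10
    n_runs_crossval: int = 1               # starts per cross-validation fit
    seed: int = 0
    population_grid: tuple = (0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)
    start_noise: float = 0.5               # Angstrom, random-start sigma
    maxiter: int = 600

    def __post_init__(self):
        if self.max_displacement <= 0:
            raise ValueError("max displacement must be positive")
        if self.n_keep > self.n_runs:
            raise ValueError("n_keep must not exceed n_runs")


def add_protons(structure: StructureModel) -> StructureModel:
    """Return a copy with ideal-geometry amide and alpha protons added
    where missing (files are never required to contain hydrogens)."""
    model = structure.copy()
    new: list[Atom] = []
    for r in model.residue_numbers():
        resname = model.resname(r)
        chain = next(a.chain for a in model.atoms if a.resnum == r)
        if (not model.has_atom(r, "H") and resname != "PRO"
                and model.has_atom(r, "N") and model.has_atom(r, "CA")
                and model.has_atom(r - 1, "C")):
            h = geometry.build_amide_h(model.coord(r, "N"),
                                       model.coord(r, "CA"),
                                       model.coord(r - 1, "C"))
            new.append(Atom(chain, r, resname, "H", "H", h))
        if (not model.has_atom(r, "HA") and not model.has_atom(r, "HA2")
                and model.has_atom(r, "N") and model.has_atom(r, "CA")
                and model.has_atom(r, "C")):
            ca = model.coord(r, "CA")
            n_, c_ = model.coord(r, "N"), model.coord(r, "C")
            if model.has_atom(r, "CB"):
                ha = geometry.build_ha(ca, n_, c_, model.coord(r, "CB"))
            else:
                ha = geometry.build_ha_gly(ca, n_, c_)
            new.append(Atom(chain, r, resname, "HA", "H", ha))
    if not new:
        return model
    atoms = sorted(model.atoms + new, key=lambda a: a.resnum)
    return StructureModel(atoms, model.het_atoms, model.metadata)


# ---------------------------------------------------------------------------
# energy model

RESIDUE_BONDS = [("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"),
                 ("CA", "C"), ("C", "O")]


def local_geometry_pairs(structure: StructureModel):
    """Elastic-network pair list preserving local covalent geometry:
    bonded plus 1-3 and 1-4 atom pairs, with reference distances taken
    from `structure`. Returns (pair_i, pair_j, d0, atom_index)."""
    atoms = structure.atoms
    index = {(a.resnum, a.name): i for i, a in enumerate(atoms)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}

    def link(r1, n1, r2, n2):
        i = index.get((r1, n1))
        j = index.get((r2, n2))
        if i is not None and j is not None:
            adj[i].add(j)
            adj[j].add(i)

    for r in structure.residue_numbers():
        for a, b in RESIDUE_BONDS:
            link(r, a, r, b)
        link(r, "C", r + 1, "N")
    pairs = set()
    for i in adj:
        seen = {i: 0}
        frontier = [i]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, d in seen.items():
            if d >= 1 and i < v:
                pairs.add((i, v))
    pair_i = np.array([p[0] for p in sorted(pairs)])
    pair_j = np.array([p[1] for p in sorted(pairs)])
    xyz = structure.coords()
    d0 = np.linalg.norm(xyz[pair_i] - xyz[pair_j], axis=1)
    return pair_i, pair_j, d0, index


def strip_protons(model: StructureModel) -> StructureModel:
    """Heavy-atom copy (drops amide and alpha protons)."""
    atoms = [a.copy() for a in model.atoms
             if a.name not in ("H", "HA", "HA2", "HA3")]
    return StructureModel(atoms, [a.copy() for a in model.het_atoms],
                          model.metadata)


class TwoStateRefiner:
    """Restrained Cartesian minimization of the minor conformer.

    Only heavy atoms are free coordinates; amide and alpha protons are
    rigidly rebuilt from their bonded heavy atoms at every energy
    evaluation (with chain-rule gradients), mirroring torsion-space
    refinement where proton positions carry no independent degrees of
    freedom. This keeps the per-residue orientational freedom comparable
    to the number of RDC observations and prevents lone protons from
    absorbing restraint violations.
    """

    def __init__(self, ground: StructureModel, records: list[RdcRecord],
                 tensors: dict[str, AlignmentTensor],
                 config: RefinementConfig, w: float):
        if not 0.0 < w < 1.0:
            raise ValueError("minor weight must be in (0, 1)")
        self.config = config
        self.w = w
        self.full = add_protons(ground)     # reference for ground-state RDCs
        self.ground = strip_protons(self.full)
        self.atoms = self.ground.atoms
        self.index = {(a.resnum, a.name): i for i, a in enumerate(self.atoms)}
        self.x0 = self.ground.coords()
        self.n = len(self.atoms)
        self.pair_i, self.pair_j, self.pair_d0, _ = \
            local_geometry_pairs(self.ground)
        self.virt: list = []                # (base, partners, length)
        self.virt_id: dict = {}
        self._build_rdc(records, tensors)
        self._group_virtuals()
        self._build_dihedrals(config.dihedral_restraints)

    # -- setup -------------------------------------------------------------
    def _virtual(self, resnum: int, name: str):
        """Index (into the extended position array) of a rigidly
        constructed proton; None if it cannot be built."""
        key = (resnum, name)
        if key in self.virt_id:
            return self.virt_id[key]
        if name == "H":
            if self.ground.resname(resnum) == "PRO":
                return None
            base = self.index.get((resnum, "N"))
            parts = [self.index.get((resnum - 1, "C")),
                     self.index.get((resnum, "CA"))]
            length = 1.041
        elif name == "HA":
            base = self.index.get((resnum, "CA"))
            parts = [self.index.get((resnum, "N")),
                     self.index.get((resnum, "C")),
                     self.index.get((resnum, "CB"))]
            length = 1.117
        else:
            return None
        if base is None or any(p is None for p in parts):
            return None
        vid = self.n + len(self.virt)
        self.virt.append((base, parts, length))
        self.virt_id[key] = vid
        return vid

    def _build_rdc(self, records, tensors):
        vm = vector_map(build_bond_vectors(self.full))
        atom_of = {"NH": (("N", 0), ("H", 0)), "CAHA": (("CA", 0), ("HA", 0)),
                   "NC": (("N", 0), ("C", -1)), "HNC": (("H", 0), ("C", -1))}
        ia, ib, mats, obs_eff, kw, keys = [], [], [], [], [], []
        skipped = 0
        for rec in records:
            v = vm.get((rec.resnum, rec.coupling_type))
            (na, oa), (nb, ob) = atom_of[rec.coupling_type]
            i = (self.index.get((rec.resnum + oa, na)) if na not in ("H", "HA")
                 else self._virtual(rec.resnum + oa, na))
            j = (self.index.get((rec.resnum + ob, nb)) if nb not in ("H", "HA")
                 else self._virtual(rec.resnum + ob, nb))
            if v is None or i is None or j is None:
                skipped += 1
                continue
            tensor = tensors[rec.medium]
            d_ground = float(back_calc_rdc([v], tensor)[0])
            k_set = self.config.rdc_weights.get(
                (rec.medium, rec.coupling_type), 1.0) * self.config.k_rdc
            ia.append(i)
            ib.append(j)
            mats.append(v.dmax * tensor.matrix)
            obs_eff.append(rec.value - (1.0 - self.w) * d_ground)
            kw.append(k_set / rec.error ** 2)
            keys.append((rec.medium, rec.coupling_type, rec.resnum))
        if skipped:
            log.info("refinement: %d RDC records without usable vectors", skipped)
        self.rdc_ia = np.array(ia, dtype=int)
        self.rdc_ib = np.array(ib, dtype=int)
        self.rdc_mats = np.array(mats) if mats else np.empty((0, 3, 3))
        self.rdc_obs_eff = np.array(obs_eff)
        self.rdc_kw = np.array(kw)
        self.rdc_keys = keys

    def _group_virtuals(self):
        """Batch the constructed protons by partner count for vectorized
        position building and gradient backpropagation."""
        self._vgroups = []
        for n_part in (2, 3):
            sel = [k for k, (_, ps, _) in enumerate(self.virt)
                   if len(ps) == n_part]
            if sel:
                self._vgroups.append((
                    np.array(sel),
                    np.array([self.virt[k][0] for k in sel]),
                    np.array([self.virt[k][1] for k in sel]),
                    np.array([self.virt[k][2] for k in sel]),
                ))

    def _virtual_positions(self, x: np.ndarray):
        """Proton positions from heavy coordinates: bond of fixed length
        along the negative sum of unit vectors to the partner atoms."""
        h = np.zeros((len(self.virt), 3))
        cache = []
        for sel, base, parts, lengths in self._vgroups:
            b = x[base]
            d = x[parts] - b[:, None, :]
            r = np.linalg.norm(d, axis=2)
            u = d / r[..., None]
            s = -u.sum(axis=1)
            ns = np.linalg.norm(s, axis=1)
            evec = s / ns[:, None]
            h[sel] = b + lengths[:, None] * evec
            cache.append((sel, base, parts, lengths, r, u, ns, evec))
        return h, cache

    def _backprop_virtuals(self, gh_all: np.ndarray, cache, g: np.ndarray):
        for sel, base, parts, lengths, r, u, ns, evec in cache:
            gh = gh_all[sel]
            gs = lengths[:, None] * (
                gh - evec * np.einsum("mi,mi->m", evec, gh)[:, None]
            ) / ns[:, None]
            proj = gs[:, None, :] - u * np.einsum("mpi,mi->mp", u, gs)[..., None]
            gp = -proj / r[..., None]
            np.add.at(g, parts, gp)
            np.add.at(g, base, gh - gp.sum(axis=1))

    def _build_dihedrals(self, restraints):
        quads, targets, hws = [], [], []
        for d in restraints:
            if d.angle == "phi":
                names = [(d.resnum - 1, "C"), (d.resnum, "N"),
                         (d.resnum, "CA"), (d.resnum, "C")]
            elif d.angle == "psi":
                names = [(d.resnum, "N"), (d.resnum, "CA"),
                         (d.resnum, "C"), (d.resnum + 1, "N")]
            elif d.angle == "omega":
                names = [(d.resnum, "CA"), (d.resnum, "C"),
                         (d.resnum + 1, "N"), (d.resnum + 1, "CA")]
            else:
                raise ValueError(f"unknown dihedral angle {d.angle!r}")
            idx = [self.index.get(k) for k in names]
            if any(i is None for i in idx):
                log.warning("dihedral restraint %s %d: atoms missing, skipped",
                            d.angle, d.resnum)
                continue
            quads.append(idx)
            targets.append(np.deg2rad(d.target_deg))
            hws.append(np.deg2rad(d.halfwidth_deg))
        self.dihe_idx = np.array(quads, dtype=int) if quads else np.empty((0, 4), int)
        self.dihe_target = np.array(targets)
        self.dihe_hw = np.array(hws)

    # -- energy ------------------------------------------------------------
    def energy_grad(self, x_flat: np.ndarray) -> tuple[float, np.ndarray]:
        x = x_flat.reshape(self.n, 3)
        g = np.zeros_like(x)
        cfg = self.config
        # elastic local geometry
        d_vec = x[self.pair_i] - x[self.pair_j]
        d = np.linalg.norm(d_vec, axis=1)
        dd = d - self.pair_d0
        e = cfg.k_geom * float(dd @ dd)
        coef = (2.0 * cfg.k_geom * dd / np.maximum(d, 1e-9))[:, None] * d_vec
        np.add.at(g, self.pair_i, coef)
        np.add.at(g, self.pair_j, -coef)
        # displacement cap
        disp = x - self.x0
        r = np.linalg.norm(disp, axis=1)
        excess = np.maximum(r - cfg.max_displacement, 0.0)
        e += cfg.k_disp * float(excess @ excess)
        coef = (2.0 * cfg.k_disp * excess / np.maximum(r, 1e-9))[:, None] * disp
        g += coef
        # population-weighted RDC (on heavy + rigidly built proton positions)
        if len(self.rdc_ia):
            if self.virt:
                hpos, cache = self._virtual_positions(x)
                pos = np.vstack([x, hpos])
            else:
                pos, cache = x, []
            u = pos[self.rdc_ib] - pos[self.rdc_ia]
            norm = np.linalg.norm(u, axis=1)
            v = u / norm[:, None]
            mv = np.einsum("nij,nj->ni", self.rdc_mats, v)
            d_minor = np.einsum("ni,ni->n", v, mv)
            resid = self.rdc_obs_eff - self.w * d_minor
            e += float(self.rdc_kw @ (resid * resid))
            dd_du = 2.0 * (mv - d_minor[:, None] * v) / norm[:, None]
            coef = (-2.0 * self.rdc_kw * resid * self.w)[:, None] * dd_du
            gpos = np.zeros_like(pos)
            np.add.at(gpos, self.rdc_ib, coef)
            np.add.at(gpos, self.rdc_ia, -coef)
            g += gpos[:self.n]
            if self.virt:
                self._backprop_virtuals(gpos[self.n:], cache, g)
        # flat-bottom dihedral restraints
        if len(self.dihe_idx):
            p0 = x[self.dihe_idx[:, 0]]
            p1 = x[self.dihe_idx[:, 1]]
            p2 = x[self.dihe_idx[:, 2]]
            p3 = x[self.dihe_idx[:, 3]]
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            phi = np.arctan2(np.einsum("ni,ni->n", np.cross(n1, n2), b2) / nb2,
                             np.einsum("ni,ni->n", n1, n2))
            delta = np.arctan2(np.sin(phi - self.dihe_target),
                               np.cos(phi - self.dihe_target))
            excess = np.sign(delta) * np.maximum(np.abs(delta) - self.dihe_hw, 0.0)
            e += cfg.k_dihe * float(excess @ excess)
            de_dphi = 2.0 * cfg.k_dihe * excess
            n1sq = np.einsum("ni,ni->n", n1, n1)
            n2sq = np.einsum("ni,ni->n", n2, n2)
            gp0 = -(nb2 / np.maximum(n1sq, 1e-12))[:, None] * n1
            gp3 = (nb2 / np.maximum(n2sq, 1e-12))[:, None] * n2
            c12 = (np.einsum("ni,ni->n", b1, b2) / nb2 ** 2)[:, None]
            c32 = (np.einsum("ni,ni->n", b3, b2) / nb2 ** 2)[:, None]
            gp1 = -(1.0 + c12) * gp0 + c32 * gp3
            gp2 = c12 * gp0 - (1.0 + c32) * gp3
            for idx_col, gp in zip(self.dihe_idx.T, (gp0, gp1, gp2, gp3)):
                np.add.at(g, idx_col, de_dphi[:, None] * gp)
        return e, g.ravel()

    # -- minimization ------------------------------------------------------
    def prerelax(self, x_start: np.ndarray, maxiter: int = 300) -> np.ndarray:
        """Relax a randomly perturbed start under the geometry and
        displacement terms alone, so the full minimization begins from a
        chemically regular conformer."""
        cfg = self.config

        def fg(x_flat):
            x = x_flat.reshape(self.n, 3)
            g = np.zeros_like(x)
            dv = x[self.pair_i] - x[self.pair_j]
            d = np.linalg.norm(dv, axis=1)
            dd = d - self.pair_d0
            e = cfg.k_geom * float(dd @ dd)
            coef = (2.0 * cfg.k_geom * dd / np.maximum(d, 1e-9))[:, None] * dv
            np.add.at(g, self.pair_i, coef)
            np.add.at(g, self.pair_j, -coef)
            disp = x - self.x0
            r = np.linalg.norm(disp, axis=1)
            excess = np.maximum(r - cfg.max_displacement, 0.0)
            e += cfg.k_disp * float(excess @ excess)
            g += (2.0 * cfg.k_disp * excess / np.maximum(r, 1e-9))[:, None] * disp
            return e, g.ravel()

        res = minimize(fg, x_start.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxcor": 20})
        return res.x.reshape(self.n, 3)

    def run(self, x_start: np.ndarray) -> tuple[np.ndarray, float, bool]:
        res = minimize(lambda x: self.energy_grad(x), x_start.ravel(),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": self.config.maxiter, "maxcor": 20})
        return res.x.reshape(self.n, 3), float(res.fun), bool(np.isfinite(res.fun))

    def minor_model(self, xyz: np.ndarray) -> StructureModel:
        return self.ground.with_coords(xyz)

    def ensemble_prediction(self, minor: StructureModel,
                            records: list[RdcRecord],
                            tensors: dict[str, AlignmentTensor]) -> np.ndarray:
        ens = EnsembleModel([self.ground, minor], [1.0 - self.w, self.w])
        from .rdc import ensemble_rdc
        return ensemble_rdc(ens, records, tensors)


def refine_two_state(ground: StructureModel, records: list[RdcRecord],
                     tensors: dict[str, AlignmentTensor],
                     config: RefinementConfig, w: float,
                     n_runs: int | None = None,
                     rng: np.random.Generator | None = None):
    """Refine the minor conformer from `n_runs` random perturbed starts.

    Returns (refiner, runs) where runs is a list of (EnsembleModel, energy)
    sorted by energy; runs whose displacement exceeds the cap beyond a 10%
    tolerance are discarded and logged.
    """
    refiner = TwoStateRefiner(ground, records, tensors, config, w)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_runs = config.n_runs if n_runs is None else n_runs
    runs = []
    attempts = 0
    while len(runs) < n_runs and attempts < 3 * n_runs:
        attempts += 1
        x_start = refiner.x0 + rng.normal(0.0, config.start_noise,
                                          refiner.x0.shape)
        x_start = refiner.prerelax(x_start)
        xyz, energy, ok = refiner.run(x_start)
        if not ok:
            log.warning("refinement run diverged; discarded")
            continue
        max_disp = float(np.linalg.norm(xyz - refiner.x0, axis=1).max())
        if max_disp > config.max_displacement * 1.1:
            log.warning("run exceeds displacement cap (%.2f A); discarded",
                        max_disp)
            continue
        minor = refiner.minor_model(xyz)
        ens = EnsembleModel([refiner.ground, minor], [1.0 - w, w])
        runs.append((ens, energy))
    if not runs:
        raise RuntimeError("no refinement run converged")
    runs.sort(key=lambda t: t[1])
    return refiner, runs


def select_reporting_ensemble(runs, n_keep: int):
    """The n_keep lowest-energy minor conformers with spread statistics."""
    if n_keep > len(runs):
        raise ValueError("fewer converged runs than n_keep")
    kept = runs[:n_keep]
    minors = [ens.conformers[1] for ens, _ in kept]
    ground = kept[0][0].conformers[0]
    from .compare import ensemble_rmsd_stats
    stats = ensemble_rmsd_stats(minors, ground)
    return {
        "minors": minors,
        "energies": [e for _, e in kept],
        "rmsd_to_mean": stats["mean_rmsd_to_mean"],
        "rmsd_to_ground_range": stats["rmsd_to_reference_range"],
    }


def _rdc_sets(records):
    sets: dict[tuple[str, str], list[RdcRecord]] = {}
    for r in records:
        sets.setdefault((r.medium, r.coupling_type), []).append(r)
    return sets


def crossval_rfree(ground: StructureModel, records: list[RdcRecord],
                   tensors: dict[str, AlignmentTensor],
                   config: RefinementConfig, w: float,
                   holdout_sets=None) -> dict:
    """Leave-one-set-out cross-validation.

    For each RDC set (medium, coupling type), refines with every other set
    and scores the held-out set with the R-free factor of the weighted
    two-state prediction; the R factor of the held-out set against the
    ground conformer alone (N=1) is reported for comparison.
    """
    sets = _rdc_sets(records)
    if len(sets) < 2:
        raise ValueError("cross-validation needs >=2 RDC sets")
    keys = list(sets) if holdout_sets is None else [tuple(k) for k in holdout_sets]
    rng = np.random.default_rng(config.seed)
    out = {}
    ground_h = add_protons(ground)
    gvm = vector_map(build_bond_vectors(ground_h))
    for key in keys:
        held = sets[key]
        train = [r for r in records if (r.medium, r.coupling_type) != key]
        refiner, runs = refine_two_state(ground, train, tensors, config, w,
                                         n_runs=config.n_runs_crossval, rng=rng)
        best_minor = runs[0][0].conformers[1]
        usable = [r for r in held if (r.resnum, r.coupling_type) in gvm]
        obs = np.array([r.value for r in usable])
        pred_n2 = refiner.ensemble_prediction(best_minor, usable, tensors)
        vecs = [gvm[(r.resnum, r.coupling_type)] for r in usable]
        pred_n1 = back_calc_rdc(vecs, tensors[key[0]])
        da_t = tensors[key[0]].da * DMAX_RATIO[key[1]]
        rh = tensors[key[0]].rhombicity
        fq2 = quality_factors(obs, pred_n2, da_t, rh, r_free=True)
        fq1 = quality_factors(obs, pred_n1, da_t, rh)
        out[key] = {"r_free_n2": fq2.r_free, "r_n1": fq1.r_factor,
                    "rmsd_n2": fq2.rmsd, "rmsd_n1": fq1.rmsd,
                    "n": fq2.n_restraints}
    return out


def population_grid_search(ground: StructureModel, records: list[RdcRecord],
                           tensors: dict[str, AlignmentTensor],
                           config: RefinementConfig,
                           holdout_sets=None) -> dict:
    """Repeat cross-validated refinement over a grid of minor populations.

    The optimum is the fraction minimizing the summed cross-validated
    R-free. No identifiable optimum is declared (the one-state situation)
    when the minimum sits at a grid edge or when even the best fraction
    shows no cross-validated improvement over the single-conformer fit.
    """
    grid = list(config.population_grid)
    if not grid:
        raise ValueError("empty population grid")
    table = {}
    for w in grid:
        cv = crossval_rfree(ground, records, tensors, config, w, holdout_sets)
        table[w] = {
            "sum_r_free": float(sum(v["r_free_n2"] for v in cv.values())),
            "sum_r_n1": float(sum(v["r_n1"] for v in cv.values())),
            "per_set": cv,
        }
    sums = np.array([table[w]["sum_r_free"] for w in grid])
    i_best = int(np.argmin(sums))
    best = grid[i_best]
    at_edge = i_best in (0, len(grid) - 1) and len(grid) > 2
    no_improvement = table[best]["sum_r_free"] >= table[best]["sum_r_n1"]
    return {"optimal_w": float(best), "flat": bool(at_edge or no_improvement),
            "table": table, "grid": grid}


def calibrate_rdc_weight(ground, records, tensors, config, w,
                         rmsd_band=(0.5, 1.0), n_bisect: int = 6):
    """Bisection on the global RDC weight so the refined ensemble fits the
    N-H couplings within the experimental band but not tighter.

    Returns a config with the adjusted k_rdc.
    """
    lo, hi = 0.01, 100.0
    cfg = config
    for _ in range(n_bisect):
        mid = float(np.sqrt(lo * hi))
        cfg = replace(config, k_rdc=mid)
        refiner, runs = refine_two_state(ground, records, tensors, cfg, w,
                                         n_runs=1)
        minor = runs[0][0].conformers[1]
        nh = [r for r in records if r.coupling_type == "NH"]
        pred = refiner.ensemble_prediction(minor, nh, tensors)
        obs = np.array([r.value for r in nh])
        rmsd = float(np.sqrt(np.mean((obs - pred) ** 2)))
        if rmsd > rmsd_band[1]:
            lo = mid
        elif rmsd < rmsd_band[0]:
            hi = mid
        else:
            break
    return cfg
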