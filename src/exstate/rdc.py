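"""Residual dipolar coupling geometry and statistics.

An RDC measured under weak alignment reports the orientation of an
internuclear vector relative to the molecular alignment (Saupe) tensor:
D = Dmax * v^T S v, equivalently Da[(3cos^2 theta - 1) + (3/2) R sin^2 theta
cos 2 phi] in the tensor eigenframe, with magnitude Da and rhombicity
R in [0, 2/3]. All couplings are kept on the amide N-H scale, so the fitted
Saupe tensor carries units of Hz and Da is reported in Hz on that scale.

The tensor is fitted by singular-value decomposition of the five-column
direction-cosine design matrix (rows weighted by 1/error and normalized by
the type-specific dipolar constant). Because a single RDC set samples bond
orientations sparsely and with orientational noise, the SVD-fitted tensor
magnitude is systematically underestimated while the rhombicity is not;
:func:`correct_tensor_magnitude` compensates by a grid search over a common
magnitude scale factor that minimizes the summed R factor over all coupling
types measured in one alignment medium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .constants import COUPLING_TYPES, DMAX_RATIO
from .formats_io import RdcRecord, StructureModel
from . import geometry

log = logging.getLogger("exstate")


@dataclass(frozen=True)
class BondVector:
    resnum: int
    coupling_type: str
    vector: np.ndarray  # unit, molecular frame
    dmax: float         # dipolar constant relative to N-H


@dataclass(frozen=True)
class AlignmentTensor:
    """Saupe order tensor in Hz on the N-H scale.

    `saupe` holds the five independent components
    (Sxx, Syy, Sxy, Sxz, Syz); Szz = -(Sxx + Syy).
    """

    saupe: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "saupe", np.asarray(self.saupe, float))
        if self.saupe.shape != (5,):
            raise ValueError("saupe vector must have 5 components")

    @property
    def matrix(self) -> np.ndarray:
        sxx, syy, sxy, sxz, syz = self.saupe
        return np.array([[sxx, sxy, sxz],
                         [sxy, syy, syz],
                         [sxz, syz, -sxx - syy]])

    def _eig(self):
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))  # |Sxx| <= |Syy| <= |Szz|
        return w[order], v[:, order]

    @property
    def da(self) -> float:
        """Magnitude, Hz on the N-H scale (axial component / 2)."""
        w, _ = self._eig()
        return float(w[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        w, _ = self._eig()
        return float((2.0 / 3.0) * (w[0] - w[1]) / w[2])

    @property
    def euler_angles(self) -> tuple[float, float, float]:
        """z-y-z Euler angles (deg) of the eigenframe (x, y, z) =
        (smallest, middle, largest |eigenvalue|) in the molecular frame."""
        w, v = self._eig()
        rot = v  # columns x, y, z
        if np.linalg.det(rot) < 0:
            rot = rot * np.array([1.0, 1.0, -1.0])  # keep right-handed
        beta = np.degrees(np.arccos(np.clip(rot[2, 2], -1, 1)))
        if abs(rot[2, 2]) > 1 - 1e-9:
            alpha = np.degrees(np.arctan2(rot[1, 0], rot[0, 0]))
            gamma = 0.0
        else:
            alpha = np.degrees(np.arctan2(rot[1, 2], rot[0, 2]))
            gamma = np.degrees(np.arctan2(rot[2, 1], -rot[2, 0]))
        return float(alpha), float(beta), float(gamma)

    def scaled(self, factor: float) -> "AlignmentTensor":
        """Tensor with magnitude scaled by `factor`; orientation and
        rhombicity unchanged."""
        return AlignmentTensor(self.saupe * factor)


@dataclass
class FitQuality:
    rmsd: float       # Hz
    q_factor: float
    r_factor: float
    n_restraints: int
    r_free: float | None = None


# ---------------------------------------------------------------------------
# bond vectors

def build_bond_vectors(structure: StructureModel,
                       types=COUPLING_TYPES) -> list[BondVector]:
    """Internuclear unit vectors for the requested coupling types.

    Missing amide and alpha protons are reconstructed with ideal geometry;
    proline N-H (and H^N-C') vectors are skipped, as are residues missing
    the required heavy atoms (with a logged warning).
    """
    resnums = structure.residue_numbers()
    out: list[BondVector] = []
    h_cache: dict[int, np.ndarray] = {}

    def amide_h(r: int) -> np.ndarray | None:
        if structure.has_atom(r, "H"):
            return structure.coord(r, "H")
        if r in h_cache:
            return h_cache[r]
        prev = r - 1
        if not (structure.has_atom(r, "N") and structure.has_atom(r, "CA")
                and structure.has_atom(prev, "C")):
            return None
        h = geometry.build_amide_h(structure.coord(r, "N"),
                                   structure.coord(r, "CA"),
                                   structure.coord(prev, "C"))
        h_cache[r] = h
        return h

    for r in resnums:
        resname = structure.resname(r)
        for t in types:
            if t in ("NH", "HNC") and resname == "PRO":
                continue
            if t in ("NH", "HNC"):
                a = amide_h(r) if t == "HNC" else (
                    structure.coord(r, "N") if structure.has_atom(r, "N") else None)
                b = amide_h(r) if t == "NH" else None
                if t == "NH":
                    if a is None or b is None:
                        continue
                    vec = b - a
                else:  # HNC: H(r) -> C'(r-1)
                    if a is None or not structure.has_atom(r - 1, "C"):
                        continue
                    vec = structure.coord(r - 1, "C") - a
            elif t == "CAHA":
                if not structure.has_atom(r, "CA"):
                    log.warning("residue %d: no CA, skipping CAHA", r)
                    continue
                ca = structure.coord(r, "CA")
                if structure.has_atom(r, "HA"):
                    ha = structure.coord(r, "HA")
                elif structure.has_atom(r, "HA2"):
                    ha = structure.coord(r, "HA2")
                else:
                    if not (structure.has_atom(r, "N") and structure.has_atom(r, "C")):
                        log.warning("residue %d: cannot build HA", r)
                        continue
                    n_, c_ = structure.coord(r, "N"), structure.coord(r, "C")
                    if structure.has_atom(r, "CB"):
                        ha = geometry.build_ha(ca, n_, c_, structure.coord(r, "CB"))
                    else:
                        ha = geometry.build_ha_gly(ca, n_, c_)
                vec = ha - ca
            else:  # NC
                if not (structure.has_atom(r, "N") and structure.has_atom(r - 1, "C")):
                    continue
                vec = structure.coord(r - 1, "C") - structure.coord(r, "N")
            norm = np.linalg.norm(vec)
            if norm < 1e-6:
                continue
            out.append(BondVector(r, t, vec / norm, DMAX_RATIO[t]))
    return out


def vector_map(vectors: list[BondVector]) -> dict[tuple[int, str], BondVector]:
    return {(v.resnum, v.coupling_type): v for v in vectors}


# ---------------------------------------------------------------------------
# tensor fitting and back-calculation

def _design_row(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([x * x - z * z, y * y - z * z,
                     2 * x * y, 2 * x * z, 2 * y * z])


def back_calc_rdc(vectors: list[BondVector],
                  tensor: AlignmentTensor) -> np.ndarray:
    """Predicted couplings (Hz) D = Dmax * v^T S v."""
    if not vectors:
        return np.empty(0)
    a = np.array([_design_row(v.vector) for v in vectors])
    dmax = np.array([v.dmax for v in vectors])
    return dmax * (a @ tensor.saupe)


def quality_factors(observed, predicted, da: float, rhombicity: float,
                    r_free: bool = False) -> FitQuality:
    """RMSD, Q and R quality factors for paired coupling lists.

    Q normalizes by the observed RMS; R normalizes by the RMS expected for
    randomly distributed bond vectors, sqrt(2 Da^2 (4 + 3R^2) / 5), with Da
    on the same scale as `observed`.
    """
    obs = np.asarray(observed, float)
    calc = np.asarray(predicted, float)
    if obs.size == 0 or obs.shape != calc.shape:
        raise ValueError("need equally sized, non-empty coupling lists")
    rmsd = float(np.sqrt(np.mean((obs - calc) ** 2)))
    q = rmsd / float(np.sqrt(np.mean(obs ** 2)))
    denom = np.sqrt(2.0 * da ** 2 * (4.0 + 3.0 * rhombicity ** 2) / 5.0)
    r = rmsd / denom
    fq = FitQuality(rmsd=rmsd, q_factor=q, r_factor=float(r),
                    n_restraints=len(obs))
    if r_free:
        fq.r_free = float(r)
    return fq


def svd_fit_tensor(vectors: list[BondVector], observed: list[RdcRecord],
                   rcond: float = 0.05) -> tuple[AlignmentTensor, FitQuality]:
    """Least-squares Saupe tensor from observed couplings by SVD.

    Rows are weighted by 1/error; couplings of different types are first
    normalized by their dipolar constants so every type contributes on the
    N-H scale. Singular values below `rcond` times the largest are
    truncated, which stabilizes fits to sparse, orientationally anisotropic
    sets (e.g. the nearly parallel N-H vectors of a single helix) at the
    cost of shrinking the fitted tensor along unsampled directions -- the
    origin of the sparsity underestimate of the tensor magnitude that
    :func:`correct_tensor_magnitude` compensates. Raises if fewer than five
    linearly independent orientations are available. Quality factors are
    computed on the normalized scale.
    """
    vm = vector_map(vectors)
    rows, b, w = [], [], []
    for rec in observed:
        v = vm.get((rec.resnum, rec.coupling_type))
        if v is None:
            log.warning("no bond vector for %s %d; record skipped",
                        rec.coupling_type, rec.resnum)
            continue
        rows.append(_design_row(v.vector))
        b.append(rec.value / v.dmax)          # normalize to N-H scale
        w.append(abs(v.dmax) / rec.error)     # 1/sigma on the same scale
    if len(rows) < 5:
        raise ValueError("need >=5 usable RDCs to fit a tensor")
    a = np.array(rows)
    b = np.array(b)
    w = np.array(w)
    if np.linalg.matrix_rank(a) < 5:
        raise ValueError("degenerate orientation sampling: design rank < 5")
    sol, *_ = np.linalg.lstsq(a * w[:, None], b * w, rcond=rcond)
    tensor = AlignmentTensor(sol)
    pred = a @ sol
    fq = quality_factors(b, pred, tensor.da, tensor.rhombicity)
    return tensor, fq


def ensemble_rdc(ensemble, records: list[RdcRecord],
                 tensors: dict[str, AlignmentTensor]) -> np.ndarray:
    """Population-weighted predicted couplings for an ensemble.

    `ensemble` provides `.conformers` (StructureModels sharing numbering)
    and `.weights` (summing to 1); `tensors` maps medium id to its fixed
    alignment tensor. Returns predictions aligned with `records`.
    """
    weights = np.asarray(ensemble.weights, float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("ensemble weights must sum to 1")
    pred = np.zeros(len(records))
    for w, conf in zip(weights, ensemble.conformers, strict=True):
        vm = vector_map(build_bond_vectors(conf))
        for i, rec in enumerate(records):
            v = vm.get((rec.resnum, rec.coupling_type))
            if v is None:
                raise ValueError(f"conformer lacks vector for "
                                 f"{rec.coupling_type} {rec.resnum}")
            tensor = tensors[rec.medium]
            pred[i] += w * v.dmax * (_design_row(v.vector) @ tensor.saupe)
    return pred


# ---------------------------------------------------------------------------
# sparsity correction

@dataclass
class TensorCorrection:
    medium: str
    scale: float                       # selected common magnitude factor
    corrected: AlignmentTensor         # joint-fit tensor, magnitude scaled
    joint: AlignmentTensor             # uncorrected joint SVD fit
    per_set_svd: dict                  # coupling type -> AlignmentTensor
    summed_r: dict                     # scale -> summed R factor
    increase_pct: dict                 # type -> corrected Da vs set SVD Da, %
    bracketed: bool                    # interior minimum on the grid


def correct_tensor_magnitude(structure: StructureModel,
                             records: list[RdcRecord],
                             scale_grid=None) -> TensorCorrection:
    """Sparsity correction of the alignment-tensor magnitude for one medium.

    Fits the tensor jointly over all coupling types measured in the medium,
    then grid-searches a common scale factor (default 1.00-1.20, step 0.01)
    applied to the tensor magnitude -- orientation and rhombicity fixed --
    selecting the scale that minimizes the summed R factor over all types.
    """
    media = {r.medium for r in records}
    if len(media) != 1:
        raise ValueError(f"records must come from one medium, got {media}")
    medium = media.pop()
    types = sorted({r.coupling_type for r in records})
    if len(types) < 2:
        raise ValueError("need >=2 coupling types for the magnitude correction")
    if scale_grid is None:
        scale_grid = np.arange(1.00, 1.20 + 1e-9, 0.01)
    vectors = build_bond_vectors(structure, tuple(types))
    joint, _ = svd_fit_tensor(vectors, records)
    per_set = {}
    for t in types:
        sub = [r for r in records if r.coupling_type == t]
        try:
            per_set[t], _ = svd_fit_tensor(vectors, sub)
        except ValueError:
            log.warning("medium %s: cannot SVD-fit type %s alone", medium, t)
    vm = vector_map(vectors)
    summed_r = {}
    for s in scale_grid:
        tensor_s = joint.scaled(float(s))
        total = 0.0
        for t in types:
            sub = [r for r in records if r.coupling_type == t]
            obs = np.array([r.value for r in sub])
            vecs = [vm[(r.resnum, r.coupling_type)] for r in sub
                    if (r.resnum, r.coupling_type) in vm]
            obs = np.array([r.value for r in sub
                            if (r.resnum, r.coupling_type) in vm])
            pred = back_calc_rdc(vecs, tensor_s)
            da_t = tensor_s.da * DMAX_RATIO[t]
            total += quality_factors(obs, pred, da_t,
                                     tensor_s.rhombicity).r_factor
        summed_r[float(s)] = float(total)
    scales = np.array(sorted(summed_r))
    values = np.array([summed_r[s] for s in scales])
    best = int(np.argmin(values))
    bracketed = 0 < best < len(scales) - 1
    if not bracketed:
        log.info("medium %s: scale grid optimum at the %.2f edge "
                 "(no interior minimum)", medium, scales[best])
    corrected = joint.scaled(float(scales[best]))
    increase = {t: 100.0 * (abs(corrected.da) / abs(per_set[t].da) - 1.0)
                for t in per_set}
    return TensorCorrection(medium, float(scales[best]), corrected, joint,
                            per_set, summed_r, increase, bracketed)
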