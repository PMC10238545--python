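"""Superposition and RMSD utilities with region exclusion.

Structural comparisons exclude the conformationally variable switch
regions by default (Switch I residues 30-38, Switch II residues 59-76 in
RAS author numbering), since those regions differ between crystal forms
and carry no NMR restraints. Pairing is by (residue number, atom name)
intersection; residues missing in either model are skipped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import StructureModel
from .geometry import kabsch

log = logging.getLogger("exstate")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Conventional RAS regions, inclusive author-numbering ranges.
SWITCH_REGIONS = {"switch1": [(30, 38)], "switch2": [(59, 76)]}

#: Residues with the most significant RDC-orientation changes, used when
#: reporting cross-validation improvements.
REPORTING_RANGES = [(7, 7), (13, 15), (23, 29), (43, 54), (60, 63), (73, 81),
                    (86, 86), (92, 95), (105, 113), (120, 124), (137, 140),
                    (144, 150)]


@dataclass
class RegionSelection:
    """Named inclusive residue ranges in author numbering."""

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, ranges in self.regions.items():
            if not ranges:
                raise ValueError(f"region {name!r} is empty")
            for a, b in ranges:
                if b < a:
                    raise ValueError(f"region {name!r}: bad range {a}-{b}")

    def residues(self, names=None) -> set[int]:
        out: set[int] = set()
        for name, ranges in self.regions.items():
            if names is not None and name not in names:
                continue
            for a, b in ranges:
                out.update(range(a, b + 1))
        return out

    @classmethod
    def switches(cls) -> "RegionSelection":
        return cls(dict(SWITCH_REGIONS))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # (3, 3), proper
    translation: np.ndarray
    rmsd: float            # Angstrom
    n_atoms: int
    selection: str


def _paired_coords(mobile: StructureModel, reference: StructureModel,
                   atoms=BACKBONE_ATOMS, excluded: set[int] | None = None):
    excluded = excluded or set()
    shared = [r for r in mobile.residue_numbers()
              if r in set(reference.residue_numbers()) and r not in excluded]
    skipped = (set(mobile.residue_numbers()) ^ set(reference.residue_numbers()))
    if skipped - excluded:
        log.info("superpose: %d residues missing in one model, skipped",
                 len(skipped - excluded))
    mob, ref, used = [], [], []
    for r in shared:
        for name in atoms:
            if mobile.has_atom(r, name) and reference.has_atom(r, name):
                mob.append(mobile.coord(r, name))
                ref.append(reference.coord(r, name))
                used.append((r, name))
    return np.array(mob), np.array(ref), used


def superpose(mobile: StructureModel, reference: StructureModel,
              atoms=BACKBONE_ATOMS,
              exclusions: RegionSelection | None = None,
              exclude_names=None) -> SuperpositionResult:
    """Optimal least-squares superposition (Kabsch) of paired atoms.

    `atoms` selects the atom names compared (backbone N/CA/C/O by default,
    or e.g. ("CA",)); `exclusions` removes named regions (all named regions
    in the selection, or the subset `exclude_names`).
    """
    excluded = exclusions.residues(exclude_names) if exclusions else set()
    mob, ref, used = _paired_coords(mobile, reference, atoms, excluded)
    if len(mob) < 3:
        raise ValueError("fewer than 3 paired atoms after selection")
    rot, trans, rmsd = kabsch(mob, ref)
    _, _, rmsd_improper = kabsch(mob, ref, allow_reflection=True)
    if rmsd_improper < 0.5 * rmsd:
        raise ValueError("superposition requires a reflection: "
                         "chirality mismatch between models")
    desc = f"{len(used)} atoms ({','.join(atoms)}); excluded {sorted(excluded)[:4]}..." \
        if excluded else f"{len(used)} atoms ({','.join(atoms)})"
    return SuperpositionResult(rot, trans, rmsd, len(used), desc)


def apply_superposition(model: StructureModel,
                        sup: SuperpositionResult) -> StructureModel:
    xyz = model.coords() @ sup.rotation.T + sup.translation
    return model.with_coords(xyz)


def per_residue_displacement(mobile: StructureModel,
                             reference: StructureModel,
                             atoms=BACKBONE_ATOMS,
                             exclusions: RegionSelection | None = None
                             ) -> dict[int, float]:
    """Per-residue backbone displacement (Angstrom) after one global
    superposition on the non-excluded residues.

    Excluded residues are absent from the result, not reported as zero.
    """
    sup = superpose(mobile, reference, atoms, exclusions)
    moved = apply_superposition(mobile, sup)
    excluded = exclusions.residues() if exclusions else set()
    out: dict[int, float] = {}
    for r in moved.residue_numbers():
        if r in excluded or r not in set(reference.residue_numbers()):
            continue
        d2 = [np.sum((moved.coord(r, a) - reference.coord(r, a)) ** 2)
              for a in atoms
              if moved.has_atom(r, a) and reference.has_atom(r, a)]
        if d2:
            out[r] = float(np.sqrt(np.mean(d2)))
    return out


def ensemble_rmsd_stats(conformers: list[StructureModel],
                        reference: StructureModel,
                        atoms=BACKBONE_ATOMS,
                        exclusions: RegionSelection | None = None,
                        n_iter: int = 5) -> dict:
    """Spread of an ensemble: RMSD of each member to the iteratively
    superposed mean structure, and the range of pairwise RMSDs to a
    reference (e.g. the ground-state crystal structure)."""
    if len(conformers) < 2:
        raise ValueError("need >=2 conformers")
    excluded = exclusions.residues() if exclusions else set()
    ref0 = conformers[0]
    stacks = []
    keys = None
    for c in conformers:
        mob, _, used = _paired_coords(c, ref0, atoms, excluded)
        if keys is None:
            keys = used
        elif used != keys:
            raise ValueError("conformers do not share numbering/atom names")
        stacks.append(mob)
    coords = np.array([s.copy() for s in stacks])
    mean = coords[0].copy()
    for _ in range(n_iter):
        for i in range(len(coords)):
            rot, trans, _ = kabsch(coords[i], mean)
            coords[i] = coords[i] @ rot.T + trans
        mean = coords.mean(axis=0)
    rmsd_to_mean = [float(np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))))
                    for c in coords]
    to_ref = [superpose(c, reference, atoms, exclusions).rmsd
              for c in conformers]
    return {
        "rmsd_to_mean": rmsd_to_mean,
        "mean_rmsd_to_mean": float(np.mean(rmsd_to_mean)),
        "rmsd_to_reference": to_ref,
        "rmsd_to_reference_range": (float(min(to_ref)), float(max(to_ref))),
    }
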