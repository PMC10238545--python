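"""Structure and table I/O.

Coordinates are handled through a light-weight :class:`StructureModel`
container; parsing and writing of PDB/mmCIF files goes through gemmi.
RDC and relaxation-dispersion measurements are read from delimited text
tables (TSV or CSV, mandatory header) with a configurable column mapping,
because supplementary spreadsheets have no canonical machine format.

Residue numbering is 1-based author numbering throughout; all region
selections are inclusive ranges in that numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .constants import COUPLING_ALIASES, COUPLING_TYPES

log = logging.getLogger("exstate")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# structures

@dataclass
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    pos: np.ndarray  # (3,) Angstrom

    def copy(self) -> "Atom":
        return replace(self, pos=self.pos.copy())


@dataclass
class StructureModel:
    """Atomic model of one polypeptide chain.

    `atoms` holds the polymer ATOM records; heteroatoms (nucleotide, ions,
    waters) are retained in `het_atoms` and excluded from all backbone
    operations.
    """

    atoms: list[Atom]
    het_atoms: list[Atom] = field(default_factory=list)
    metadata: str = ""

    def __post_init__(self):
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.resnum, a.name)
            if key in self._index:
                raise FormatError(f"duplicate atom {key}")
            self._index[key] = i

    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.resnum, None)
        return list(seen)

    def resname(self, resnum: int) -> str:
        for a in self.atoms:
            if a.resnum == resnum:
                return a.resname
        raise KeyError(resnum)

    def has_atom(self, resnum: int, name: str) -> bool:
        return (resnum, name) in self._index

    def coord(self, resnum: int, name: str) -> np.ndarray:
        return self.atoms[self._index[(resnum, name)]].pos

    def set_coord(self, resnum: int, name: str, pos: np.ndarray) -> None:
        self.atoms[self._index[(resnum, name)]].pos = np.asarray(pos, float)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        atoms = [replace(a, pos=np.asarray(p, float))
                 for a, p in zip(self.atoms, xyz, strict=True)]
        return StructureModel(atoms, [a.copy() for a in self.het_atoms],
                              self.metadata)

    def copy(self) -> "StructureModel":
        return self.with_coords(self.coords())

    def validate(self) -> None:
        if not self.atoms:
            raise FormatError("empty structure")
        if not np.all(np.isfinite(self.coords())):
            raise FormatError("non-finite coordinates")
        nums = self.residue_numbers()
        for r in nums[1:-1]:
            for name in ("N", "CA", "C"):
                if not self.has_atom(r, name):
                    raise FormatError(f"residue {r} missing backbone {name}")


def read_structure(path: str, chain: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file, keeping one chain.

    Alternate locations are resolved to the highest-occupancy conformer;
    HETATM records of the chain are kept separately.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:  # gemmi raises RuntimeError
        raise FormatError(f"cannot parse structure file {path}: {e}") from e
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if not names:
            raise FormatError(f"no chains in {path}")
        chain = names[0]
    if chain not in names:
        raise FormatError(f"chain {chain!r} not in {path} (has {names})")

    atoms: list[Atom] = []
    het: list[Atom] = []
    for res in model[chain]:
        is_polymer = gemmi.find_tabulated_residue(res.name) is not None and \
            gemmi.find_tabulated_residue(res.name).is_amino_acid()
        # pick highest-occupancy altloc per atom name
        best: dict[str, gemmi.Atom] = {}
        for at in res:
            cur = best.get(at.name)
            if cur is None or at.occ > cur.occ:
                best[at.name] = at
        for name, at in best.items():
            rec = Atom(chain, res.seqid.num, res.name, name,
                       at.element.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
            (atoms if is_polymer else het).append(rec)
    if not atoms:
        raise FormatError(f"empty chain {chain!r} in {path}")
    m = StructureModel(atoms, het, metadata=st.name or "")
    if not np.all(np.isfinite(m.coords())):
        raise FormatError("non-finite coordinates")
    return m


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = model.metadata or "exstate"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in list(model.atoms) + list(model.het_atoms):
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.resnum or ch[-1].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            ch.add_residue(res)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element or a.name[0])
        at.pos = gemmi.Position(*a.pos)
        at.occ = 1.0
        ch[-1].add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# tables

@dataclass(frozen=True)
class RdcRecord:
    resnum: int
    coupling_type: str  # one of COUPLING_TYPES
    medium: str
    value: float  # Hz
    error: float  # Hz


@dataclass(frozen=True)
class DispersionRecord:
    resnum: int
    nucleus: str  # "13C-methyl" or "15N-amide"
    field_mhz: float  # 1H frequency
    temperature: float  # K
    nu_cpmg: float  # Hz
    intensity: float | None
    ref_intensity: float | None
    r2eff: float | None
    error: float | None
    replicate: int = 0


RDC_COLUMNS = {
    "resnum": ("resnum", "residue", "resid", "res"),
    "coupling_type": ("coupling_type", "type", "coupling"),
    "medium": ("medium", "medium_id", "media"),
    "value": ("value", "rdc", "d_obs", "value_hz"),
    "error": ("error", "sigma", "err", "error_hz"),
}

DISP_COLUMNS = {
    "resnum": ("resnum", "residue", "resid", "res"),
    "nucleus": ("nucleus",),
    "field_mhz": ("field_mhz", "field"),
    "temperature": ("temperature", "temperature_k", "temp_k"),
    "nu_cpmg": ("nu_cpmg", "nucpmg", "vcpmg"),
    "intensity": ("intensity", "i"),
    "ref_intensity": ("ref_intensity", "i0", "reference_intensity"),
    "r2eff": ("r2eff",),
    "error": ("error", "sigma", "err"),
    "replicate": ("replicate", "rep"),
}


def _read_table(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except FileNotFoundError:
        raise
    except Exception as e:
        raise FormatError(f"cannot parse table {path}: {e}") from e


def _map_columns(df: pd.DataFrame, schema: dict, required: tuple,
                 mapping: dict | None) -> dict[str, str]:
    cols = {c.lower().strip(): c for c in df.columns}
    out: dict[str, str] = {}
    for canon, aliases in schema.items():
        if mapping and canon in mapping:
            if mapping[canon] in df.columns:
                out[canon] = mapping[canon]
            continue
        for al in aliases:
            if al in cols:
                out[canon] = cols[al]
                break
    missing = [c for c in required if c not in out]
    if missing:
        raise FormatError(f"missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    return out


def read_rdc_table(path: str, column_mapping: dict | None = None) -> list[RdcRecord]:
    """Read an RDC table (residue, coupling type, medium, value, error).

    Rows with non-positive errors are dropped with a logged warning;
    duplicate (residue, type, medium) keys are an error.
    """
    df = _read_table(path)
    cm = _map_columns(df, RDC_COLUMNS,
                      ("resnum", "coupling_type", "medium", "value", "error"),
                      column_mapping)
    records: list[RdcRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        raw_type = str(row[cm["coupling_type"]]).strip().upper()
        ctype = COUPLING_ALIASES.get(raw_type)
        if ctype is None:
            raise FormatError(f"unknown coupling type {raw_type!r}; "
                              f"expected one of {COUPLING_TYPES}")
        err = float(row[cm["error"]])
        resnum = int(row[cm["resnum"]])
        medium = str(row[cm["medium"]]).strip()
        key = (resnum, ctype, medium)
        if key in seen:
            raise FormatError(f"duplicate RDC record for {key}")
        seen.add(key)
        if err <= 0:
            log.warning("dropping RDC row %s: non-positive error %g", key, err)
            continue
        records.append(RdcRecord(resnum, ctype, medium,
                                 float(row[cm["value"]]), err))
    return records


def write_rdc_table(records: list[RdcRecord], path: str) -> None:
    df = pd.DataFrame([{
        "resnum": r.resnum, "coupling_type": r.coupling_type,
        "medium": r.medium, "value": r.value, "error": r.error,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_dispersion_table(path: str,
                          column_mapping: dict | None = None) -> list[DispersionRecord]:
    """Read a relaxation-dispersion table.

    Each row needs (residue, temperature, nu_cpmg) plus either raw
    intensities (intensity, ref_intensity) or pre-computed (r2eff, error).
    Repeated nu_cpmg rows are kept as replicates, never merged.
    """
    df = _read_table(path)
    cm = _map_columns(df, DISP_COLUMNS, ("resnum", "temperature", "nu_cpmg"),
                      column_mapping)
    if "r2eff" not in cm and not ("intensity" in cm and "ref_intensity" in cm):
        raise FormatError("table needs either an r2eff column or "
                          "intensity + ref_intensity columns")
    records: list[DispersionRecord] = []
    rep_counter: dict[tuple, int] = {}
    for _, row in df.iterrows():
        nu = float(row[cm["nu_cpmg"]])
        if nu <= 0:
            raise FormatError(f"non-positive nu_cpmg {nu}")
        temp = float(row[cm["temperature"]])
        if not 250.0 <= temp <= 330.0:
            raise FormatError(f"temperature {temp} K outside physical range")
        inten = ref = r2 = err = None
        if "intensity" in cm and not pd.isna(row[cm["intensity"]]):
            inten = float(row[cm["intensity"]])
            ref = float(row[cm["ref_intensity"]])
            if inten <= 0 or ref <= 0:
                raise FormatError(f"non-positive intensity at nu_cpmg={nu}")
        if "r2eff" in cm and not pd.isna(row[cm["r2eff"]]):
            r2 = float(row[cm["r2eff"]])
        if "error" in cm and not pd.isna(row[cm["error"]]):
            err = float(row[cm["error"]])
            if err <= 0:
                raise FormatError(f"non-positive error at nu_cpmg={nu}")
        resnum = int(row[cm["resnum"]])
        key = (resnum, temp, nu)
        if "replicate" in cm and not pd.isna(row[cm["replicate"]]):
            rep = int(row[cm["replicate"]])
        else:
            rep = rep_counter.get(key, 0)
            rep_counter[key] = rep + 1
        records.append(DispersionRecord(
            resnum,
            str(row[cm["nucleus"]]) if "nucleus" in cm else "13C-methyl",
            float(row[cm["field_mhz"]]) if "field_mhz" in cm else 700.0,
            temp, nu, inten, ref, r2, err, rep))
    return records


def write_dispersion_table(records: list[DispersionRecord], path: str) -> None:
    df = pd.DataFrame([{
        "resnum": r.resnum, "nucleus": r.nucleus, "field_mhz": r.field_mhz,
        "temperature": r.temperature, "nu_cpmg": r.nu_cpmg,
        "intensity": r.intensity, "ref_intensity": r.ref_intensity,
        "r2eff": r.r2eff, "error": r.error, "replicate": r.replicate,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)
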