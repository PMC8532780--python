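"""Structure and tensor file I/O.

Reads and writes peptide structures (PDB / mmCIF, via gemmi) and ab initio
magnetic-resonance parameter files (magres v1.0) into a uniform internal
model: :class:`StructureModel` for atomic coordinates and
:class:`TensorRecord` for per-nucleus chemical-shielding tensors.

Coordinates are Cartesian angstroms internally; fractional CIF coordinates
are converted on read using the unit cell. Residue numbering is 1-based
(the N-terminal acetyl cap, if present, is residue 0). Only the first model
of a multi-model PDB file is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "StructureModel",
    "TensorRecord",
    "StructureParseError",
    "MagresParseError",
    "read_structure",
    "write_structure",
    "read_magres",
    "write_magres",
]


class StructureParseError(ValueError):
    """Raised when a PDB/mmCIF file violates the format or model invariants."""


class MagresParseError(ValueError):
    """Raised when a magres file is malformed."""


@dataclass
class AtomSite:
    """One atom: element, label, Cartesian position (Å), residue identity."""

    element: str
    name: str
    coords: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite values")
        if self.residue_index < 0:
            raise ValueError("residue_index must be >= 0 (0 is the acetyl cap)")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.name)


@dataclass
class StructureModel:
    """An ordered collection of atoms plus optional crystallographic metadata."""

    atoms: list[AtomSite] = field(default_factory=list)
    cell: Optional[tuple] = None  # (a, b, c, alpha, beta, gamma); None entries allowed
    space_group: Optional[str] = None

    def __post_init__(self) -> None:
        seen = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise StructureParseError(f"duplicate atom key {atom.key}")
            seen.add(atom.key)

    def add(self, atom: AtomSite) -> None:
        if atom.key in {a.key for a in self.atoms}:
            raise StructureParseError(f"duplicate atom key {atom.key}")
        self.atoms.append(atom)

    def atom(self, chain_id: str, residue_index: int, name: str) -> AtomSite:
        for a in self.atoms:
            if a.key == (chain_id, residue_index, name):
                return a
        raise KeyError((chain_id, residue_index, name))

    def get_atom(self, chain_id: str, residue_index: int, name: str) -> Optional[AtomSite]:
        try:
            return self.atom(chain_id, residue_index, name)
        except KeyError:
            return None

    def residue_indices(self, chain_id: Optional[str] = None) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if a.residue_index not in out:
                out.append(a.residue_index)
        return out

    def residue_name(self, residue_index: int, chain_id: Optional[str] = None) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index and (
                chain_id is None or a.chain_id == chain_id
            ):
                return a.residue_name
        raise KeyError(residue_index)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out


@dataclass
class TensorRecord:
    """A raw 3x3 shielding tensor (ppm, laboratory/crystal frame) at one site."""

    site_key: tuple[str, int, str]  # (chain, residue_index, atom name)
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3) or not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"tensor at {self.site_key}: need a finite 3x3 matrix")


# Residue names the pipeline knows about; anything else is retained with a warning.
_KNOWN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "AIB", "PHL", "ACE",
}


def _element_from(atom: gemmi.Atom) -> str:
    el = atom.element.name
    if el and el != "X":
        return el
    return atom.name.strip()[0]


def read_structure(path: str | Path, dialect: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``dialect`` is ``"pdb"`` or ``"mmcif"``; if omitted it is inferred from
    the file extension. Insertion codes are rejected, altloc atoms beyond the
    first are dropped, and only the first model is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")

    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    cell = None
    c = st.cell
    # gemmi fills unknown cells with a=b=c=1 Å, angles 90°; treat that as absent
    if c is not None and c.a > 0 and (c.a, c.b, c.c) != (1.0, 1.0, 1.0):
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    if dialect == "mmcif":
        cell = _mmcif_cell(path, cell)
    space_group = st.spacegroup_hm or None

    if len(st) == 0:
        return StructureModel(atoms=[], cell=cell, space_group=space_group)

    model = StructureModel(atoms=[], cell=cell, space_group=space_group)
    for chain in st[0]:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureParseError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name} {res.seqid.num} not supported"
                )
            rname = res.name.strip()
            if rname not in _KNOWN_RESIDUES:
                warnings.warn(f"unknown residue name {rname!r} retained", stacklevel=2)
            seen_names: set[str] = set()
            for atom in res:
                if atom.name in seen_names:  # altloc duplicates: keep the first
                    continue
                seen_names.add(atom.name)
                model.add(
                    AtomSite(
                        element=_element_from(atom),
                        name=atom.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_index=res.seqid.num,
                        residue_name=rname,
                        chain_id=chain.name,
                    )
                )
    return model


def _mmcif_cell(path: Path, fallback: Optional[tuple]) -> Optional[tuple]:
    """Read cell tags directly so '?'/'.' placeholders surface as None entries."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError):
        return fallback
    tags = ["_cell.length_a", "_cell.length_b", "_cell.length_c",
            "_cell.angle_alpha", "_cell.angle_beta", "_cell.angle_gamma"]
    raw = [block.find_value(t) for t in tags]
    if all(v is None for v in raw):
        return fallback
    vals = []
    missing = False
    for v in raw:
        if v is None or v in ("?", "."):
            vals.append(None)
            missing = True
        else:
            vals.append(float(gemmi.cif.as_number(v)))
    if missing:
        warnings.warn(f"{path}: unit cell has missing values", stacklevel=3)
    return tuple(vals)


def write_structure(model: StructureModel, path: str | Path, dialect: Optional[str] = None) -> Path:
    """Write a :class:`StructureModel` as PDB or mmCIF.

    ``read_structure(write_structure(m))`` preserves coordinates to 3 decimals
    for PDB and exactly (to float precision) for mmCIF.
    """
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    st = gemmi.Structure()
    st.name = "helixcst"
    if model.cell is not None and all(v is not None for v in model.cell):
        st.cell = gemmi.UnitCell(*model.cell)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    for chain_id in model.chains() or ["A"]:
        chain = gm.add_chain(gemmi.Chain(chain_id))  # gemmi add_* copies
        current_res = None
        for a in model.atoms:
            if a.chain_id != chain_id:
                continue
            if current_res is None or current_res.seqid.num != a.residue_index:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                res.het_flag = "A" if a.residue_name in _KNOWN_RESIDUES else "H"
                current_res = chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            current_res.add_atom(atom)
    st.add_model(gm)
    st.setup_entities()

    if dialect == "pdb":
        st.write_pdb(str(path))
    elif dialect == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# magres v1.0
# ---------------------------------------------------------------------------

def read_magres(
    path: str | Path,
    model: Optional[StructureModel] = None,
    chain_id: str = "A",
) -> list[TensorRecord]:
    """Parse a magres v1.0 file into :class:`TensorRecord` objects.

    Each ``ms`` line carries an atom label, an index and a row-major 3x3
    shielding tensor. Labels are interpreted as atom names and indices as
    residue indices, matching the convention :func:`write_magres` uses.
    When ``model`` is given, every record must resolve to an atom in it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    atoms: set[tuple[str, int]] = set()
    records: list[TensorRecord] = []
    in_atoms = in_magres = False
    ms_units_ok = True
    closed = {"atoms": False, "magres": False}

    for lineno, line in enumerate(lines, start=1):
        tok = line.split("#", 1)[0].split()
        if not tok:
            continue
        if tok[0] == "[atoms]":
            in_atoms = True
            continue
        if tok[0] == "[/atoms]":
            in_atoms, closed["atoms"] = False, True
            continue
        if tok[0] == "[magres]":
            in_magres = True
            continue
        if tok[0] == "[/magres]":
            in_magres, closed["magres"] = False, True
            continue
        if in_atoms:
            if tok[0] == "units":
                continue
            if tok[0] == "atom":
                if len(tok) != 7:
                    raise MagresParseError(f"{path}:{lineno}: malformed atom line")
                atoms.add((tok[2], int(tok[3])))
            continue
        if in_magres:
            if tok[0] == "units":
                if len(tok) >= 3 and tok[1] == "ms" and tok[2] != "ppm":
                    raise MagresParseError(
                        f"{path}:{lineno}: unsupported ms units {tok[2]!r}"
                    )
                continue
            if tok[0] == "ms":
                if len(tok) != 12:
                    raise MagresParseError(
                        f"{path}:{lineno}: ms line needs label, index and 9 tensor values"
                    )
                label, index = tok[1], int(tok[2])
                if atoms and (label, index) not in atoms:
                    raise MagresParseError(
                        f"{path}:{lineno}: ms references unknown atom ({label}, {index})"
                    )
                try:
                    vals = [float(v) for v in tok[3:12]]
                except ValueError as exc:
                    raise MagresParseError(f"{path}:{lineno}: {exc}") from exc
                rec = TensorRecord(
                    site_key=(chain_id, index, label),
                    matrix=np.array(vals).reshape(3, 3),
                )
                if model is not None and model.get_atom(chain_id, index, label) is None:
                    raise MagresParseError(
                        f"{path}:{lineno}: no atom ({chain_id}, {index}, {label}) in structure"
                    )
                records.append(rec)
            continue

    if (in_atoms or in_magres) or (atoms and not closed["atoms"]) or (
        records and not closed["magres"]
    ):
        raise MagresParseError(f"{path}:{len(lines)}: truncated file (unclosed block)")
    return records


def write_magres(
    model: StructureModel,
    records: Iterable[TensorRecord],
    path: str | Path,
) -> Path:
    """Write structure atoms and shielding tensors as a magres v1.0 file.

    Atom labels are atom names; the magres atom index is the residue index,
    so ``(label, index)`` keys round-trip through :func:`read_magres`.
    """
    path = Path(path)
    out = ["#$magres-abinitio-v1.0", "[atoms]", "units atom Angstrom"]
    for a in model.atoms:
        x, y, z = a.coords
        out.append(
            f"atom {a.element} {a.name} {a.residue_index} "
            f"{x:.6f} {y:.6f} {z:.6f}"
        )
    out.append("[/atoms]")
    out.append("[magres]")
    out.append("units ms ppm")
    for r in records:
        vals = " ".join(f"{v:.6f}" for v in np.asarray(r.matrix).ravel())
        out.append(f"ms {r.site_key[2]} {r.site_key[1]} {vals}")
    out.append("[/magres]")
    path.write_text("\n".join(out) + "\n")
    return path
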