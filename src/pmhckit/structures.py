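"""Uniform structural model and coordinate-file I/O.

Coordinate files (PDB or mmCIF) are parsed with gemmi and flattened into a
small, explicit object model — chains of residues of atoms, with author
numbering and insertion codes preserved — that every downstream stage
(hydrogen bonds, superposition, contacts, surface areas) consumes.  Waters
are kept separate from polymer residues.

Altloc policy: for each (residue, atom-name) the highest-occupancy conformer
is kept; ties are broken by altloc letter order, so downstream geometry is
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ParseError",
    "parse_structure",
    "write_pdb",
    "STANDARD_AA",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class ParseError(ValueError):
    """Raised for malformed or empty coordinate input."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_hetero: bool = False
    altloc: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    author_chain: str
    author_seqnum: int
    author_icode: str | None
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str | None]:
        """The author identifier (chain, seqnum, icode), unique in a Structure."""
        return (self.author_chain, self.author_seqnum, self.author_icode)

    @property
    def is_standard_aa(self) -> bool:
        return self.resname in STANDARD_AA

    @property
    def is_complete(self) -> bool:
        """Standard amino acids need N, CA, C for backbone geometry."""
        if not self.is_standard_aa:
            return True
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def __repr__(self) -> str:  # compact, for diagnostics
        icode = self.author_icode or ""
        return f"<Residue {self.resname} {self.author_chain}{self.author_seqnum}{icode}>"


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[Residue] = field(default_factory=list)

    def residues(self) -> list[Residue]:
        """All polymer residues in chain, then sequence, order."""
        out: list[Residue] = []
        for chain_id in self.chains:
            out.extend(self.chains[chain_id])
        return out

    def residue(self, chain: str, seqnum: int, icode: str | None = None) -> Residue | None:
        for res in self.chains.get(chain, []):
            if res.author_seqnum == seqnum and res.author_icode == icode:
                return res
        return None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues()) + sum(
            len(r.atoms) for r in self.waters
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A deep copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new = Structure(id=self.id)
        for chain_id, residues in self.chains.items():
            new.chains[chain_id] = [_transform_residue(r, rotation, translation) for r in residues]
        new.waters = [_transform_residue(r, rotation, translation) for r in self.waters]
        return new


def _transform_residue(res: Residue, R: np.ndarray, t: np.ndarray) -> Residue:
    return Residue(
        author_chain=res.author_chain,
        author_seqnum=res.author_seqnum,
        author_icode=res.author_icode,
        resname=res.resname,
        atoms=[
            Atom(a.name, a.element, R @ a.coords + t, a.occupancy, a.is_hetero, a.altloc)
            for a in res.atoms
        ],
    )


def parse_structure(text: str, dialect: str = "pdb", structure_id: str | None = None) -> Structure:
    """Parse coordinate-file content into a :class:`Structure`.

    Parameters
    ----------
    text:
        Full content of a PDB or mmCIF file.
    dialect:
        ``"pdb"`` or ``"mmcif"``.
    structure_id:
        Override the identifier recorded on the result.

    Only the first model is read.  One conformer is kept per atom
    (highest occupancy, ties by altloc letter).
    """
    if not text.strip():
        raise ParseError("empty coordinate input")
    if dialect not in ("pdb", "mmcif"):
        raise ParseError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed {dialect} input: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ParseError("coordinate input contains no model")
    model = st[0]

    out = Structure(id=structure_id or (st.name or "structure"))
    n_atoms = 0
    for chain in model:
        for g_res in chain:
            icode = g_res.seqid.icode.strip() or None
            res = Residue(
                author_chain=chain.name,
                author_seqnum=g_res.seqid.num,
                author_icode=icode,
                resname=g_res.name.strip(),
            )
            for atom in _select_altlocs(g_res):
                res.atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name or "X",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(float(atom.occ), 0.0), 1.0),
                        is_hetero=g_res.het_flag == "H",
                        altloc=(atom.altloc or None),
                    )
                )
            n_atoms += len(res.atoms)
            if res.resname in _WATER_NAMES:
                out.waters.append(res)
            else:
                out.chains.setdefault(chain.name, []).append(res)
    if n_atoms == 0:
        raise ParseError("coordinate input contains no atoms")
    return out


def _select_altlocs(g_res: "gemmi.Residue") -> list["gemmi.Atom"]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in g_res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occ > prev.occ or (
            math.isclose(atom.occ, prev.occ) and (atom.altloc or "~") < (prev.altloc or "~")
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` as PDB text (fixtures and reports).

    Waters are emitted last as HETATM records.  Chain identifiers longer
    than one character are truncated to their first character, which is
    unambiguous for all fixtures this package writes.
    """
    lines: list[str] = []
    serial = 1
    for res in structure.residues():
        for atom in res.atoms:
            lines.append(_pdb_atom_line(serial, atom, res, hetero=atom.is_hetero))
            serial += 1
    for res in structure.waters:
        for atom in res.atoms:
            lines.append(_pdb_atom_line(serial, atom, res, hetero=True))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # PDB column convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    icode = res.author_icode or " "
    x, y, z = atom.coords
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{res.resname:>3s} "
        f"{res.author_chain[:1]:1s}{res.author_seqnum:>4d}{icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )
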