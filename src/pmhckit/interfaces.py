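"""Contacts, polar contacts, disulfides, solvent accessibility, interfaces.

Contacts follow the convention used throughout comparative pMHC work: two
residues are in contact when any heavy-atom pair lies within 4.0 Å.  Polar
contacts are N/O/S heavy-atom pairs within 3.5 Å, optionally bridged by
waters.  Solvent-accessible surface area (SASA) is computed with the
Shrake–Rupley sphere-point method; interface summaries report per-residue
ΔSASA (complex vs. parts in isolation) and the symmetric buried area

    BSA = ½ (SASA_a,alone + SASA_b,alone − SASA_complex)

so that "exposed surface" of a ligand equals its accessible area minus the
buried part, exactly as interface servers report it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Residue, Structure

__all__ = [
    "ContactRecord",
    "PolarContact",
    "SasaResult",
    "InterfaceSummary",
    "VDW_RADII",
    "contact_residues",
    "polar_contacts",
    "detect_disulfides",
    "compute_sasa",
    "interface_summary",
    "peptide_exposed_surface",
]

#: Element-keyed van der Waals radii (Å); a single published table used for
#: every SASA computation in this package.  Unknown elements fall back to
#: the carbon radius with a warning.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.74, "NA": 2.27, "K": 2.75,
}
_DEFAULT_RADIUS = 1.70

DEFAULT_CONTACT_CUTOFF = 4.0   # Å
DEFAULT_POLAR_CUTOFF = 3.5     # Å
DEFAULT_PROBE = 1.4            # Å
DEFAULT_SPHERE_POINTS = 960
_POLAR_ELEMENTS = {"N", "O", "S"}
_SS_CUTOFF = 2.5               # Å, SG-SG


@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple[str, int, str | None]
    residue_b: tuple[str, int, str | None]
    min_atom_distance: float
    n_atom_pairs_within_cutoff: int


@dataclass(frozen=True)
class PolarContact:
    atom_a: tuple[tuple[str, int, str | None], str]  # (residue key, atom name)
    atom_b: tuple[tuple[str, int, str | None], str]
    distance: float
    water_mediated: bool = False
    water: tuple[str, int, str | None] | None = None


@dataclass
class SasaResult:
    atom_area: dict[tuple[tuple[str, int, str | None], str], float]
    residue_area: dict[tuple[str, int, str | None], float]
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.residue_area.values()))


@dataclass
class InterfaceSummary:
    part_a: str
    part_b: str
    interface_residues_a: list[tuple[str, int, str | None]]
    interface_residues_b: list[tuple[str, int, str | None]]
    buried_area: float
    dsasa_a: dict[tuple[str, int, str | None], float]
    dsasa_b: dict[tuple[str, int, str | None], float]
    contacts: list[ContactRecord] = field(default_factory=list)


def _heavy_atoms(residues: list[Residue]):
    out = []
    for res in residues:
        for atom in res.heavy_atoms():
            out.append((res, atom))
    return out


def contact_residues(group_a: list[Residue], group_b: list[Residue],
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[ContactRecord]:
    """Residue pairs with any inter-group heavy-atom pair within ``cutoff``.

    Groups must be disjoint.  Hydrogens are excluded from the distance
    test even when present.
    """
    _check_disjoint(group_a, group_b)
    atoms_a = _heavy_atoms(group_a)
    atoms_b = _heavy_atoms(group_b)
    if not atoms_a or not atoms_b or cutoff <= 0:
        return []
    xa = np.array([a.coords for _, a in atoms_a])
    xb = np.array([b.coords for _, b in atoms_b])
    tree = cKDTree(xb)
    per_pair: dict[tuple, list[float]] = {}
    for i, neighbours in enumerate(tree.query_ball_point(xa, cutoff)):
        res_a = atoms_a[i][0]
        for j in neighbours:
            res_b = atoms_b[j][0]
            d = float(np.linalg.norm(xa[i] - xb[j]))
            per_pair.setdefault((res_a.key, res_b.key), []).append(d)
    return [
        ContactRecord(
            residue_a=ka, residue_b=kb,
            min_atom_distance=min(ds),
            n_atom_pairs_within_cutoff=len(ds),
        )
        for (ka, kb), ds in sorted(per_pair.items())
    ]


def _check_disjoint(group_a: list[Residue], group_b: list[Residue]) -> None:
    keys_a = {r.key for r in group_a}
    keys_b = {r.key for r in group_b}
    overlap = keys_a & keys_b
    if overlap:
        raise ValueError(f"groups overlap on {sorted(overlap)[:5]}")


def polar_contacts(group_a: list[Residue], group_b: list[Residue],
                   cutoff: float = DEFAULT_POLAR_CUTOFF,
                   waters: list[Residue] | None = None) -> list[PolarContact]:
    """N/O/S heavy-atom pairs within ``cutoff`` between the groups.

    When ``waters`` is given, a water oxygen within ``cutoff`` of polar
    atoms of *both* groups is reported as a water-mediated contact.
    """
    _check_disjoint(group_a, group_b)

    def polar(residues):
        return [
            (res, atom) for res, atom in _heavy_atoms(residues)
            if atom.element.upper() in _POLAR_ELEMENTS
        ]

    pa, pb = polar(group_a), polar(group_b)
    out: list[PolarContact] = []
    for res_a, atom_a in pa:
        for res_b, atom_b in pb:
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            if d <= cutoff:
                out.append(PolarContact(
                    atom_a=(res_a.key, atom_a.name),
                    atom_b=(res_b.key, atom_b.name),
                    distance=d,
                ))
    if waters:
        for wat in waters:
            w_o = next((a for a in wat.heavy_atoms() if a.element.upper() == "O"), None)
            if w_o is None:
                continue
            near_a = [(r, a) for r, a in pa
                      if np.linalg.norm(a.coords - w_o.coords) <= cutoff]
            near_b = [(r, a) for r, a in pb
                      if np.linalg.norm(a.coords - w_o.coords) <= cutoff]
            for res_a, atom_a in near_a:
                for res_b, atom_b in near_b:
                    out.append(PolarContact(
                        atom_a=(res_a.key, atom_a.name),
                        atom_b=(res_b.key, atom_b.name),
                        distance=float(np.linalg.norm(atom_a.coords - w_o.coords)
                                       + np.linalg.norm(atom_b.coords - w_o.coords)),
                        water_mediated=True,
                        water=wat.key,
                    ))
    return out


def detect_disulfides(structure: Structure) -> list[tuple[tuple, tuple]]:
    """Cysteine pairs with SG-SG distance <= 2.5 Å."""
    sgs = [
        (res.key, res.coord("SG"))
        for res in structure.residues()
        if res.resname == "CYS" and res.coord("SG") is not None
    ]
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if np.linalg.norm(sgs[i][1] - sgs[j][1]) <= _SS_CUTOFF:
                out.append((sgs[i][0], sgs[j][0]))
    return out


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    if n not in _SPHERE_CACHE:
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + 5.0 ** 0.5) * k
        _SPHERE_CACHE[n] = np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
    return _SPHERE_CACHE[n]


def compute_sasa(residues: list[Residue] | Structure,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_SPHERE_POINTS,
                 radii: dict[str, float] | None = None,
                 include_waters: bool = False) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area over heavy atoms.

    Per-atom area = (unoccluded sphere-point fraction) x 4π(r+probe)².
    Waters occlude only when ``include_waters`` (they matter only for
    water-network analyses); hydrogens never do.
    """
    import warnings as _warnings

    if isinstance(residues, Structure):
        res_list = list(residues.residues())
        if include_waters:
            res_list += residues.waters
    else:
        res_list = list(residues)
    table = radii or VDW_RADII
    atoms = _heavy_atoms(res_list)
    if not atoms:
        return SasaResult({}, {}, probe, n_points)
    rads = []
    unknown = set()
    for _, atom in atoms:
        el = atom.element.upper()
        if el not in table:
            unknown.add(el)
        rads.append(table.get(el, _DEFAULT_RADIUS) + probe)
    if unknown:
        _warnings.warn(f"unknown element(s) {sorted(unknown)}: using default radius",
                       stacklevel=2)
    xyz = np.array([a.coords for _, a in atoms])
    rads = np.array(rads)
    sphere = _unit_sphere(n_points)
    tree = cKDTree(xyz)
    max_r = rads.max()
    atom_area: dict = {}
    residue_area: dict = {}
    for i, (res, atom) in enumerate(atoms):
        pts = xyz[i] + rads[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], rads[i] + max_r)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - xyz[j], axis=1)
            accessible &= d >= rads[j]
            if not accessible.any():
                break
        area = accessible.mean() * 4.0 * np.pi * rads[i] ** 2
        atom_area[(res.key, atom.name)] = float(area)
        residue_area[res.key] = residue_area.get(res.key, 0.0) + float(area)
    return SasaResult(atom_area=atom_area, residue_area=residue_area,
                      probe_radius=probe, n_sphere_points=n_points)


def interface_summary(part_a: list[Residue], part_b: list[Residue],
                      dsasa_threshold: float = 0.1,
                      name_a: str = "a", name_b: str = "b",
                      n_points: int = DEFAULT_SPHERE_POINTS,
                      contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InterfaceSummary:
    """Interface between two disjoint residue sets.

    Interface residues are those burying more than ``dsasa_threshold`` Ų
    of accessible area upon complexation (any-burial by default, the
    convention of interface servers).
    """
    if not part_a or not part_b:
        raise ValueError("interface parts must be non-empty")
    _check_disjoint(part_a, part_b)
    sasa_a = compute_sasa(part_a, n_points=n_points)
    sasa_b = compute_sasa(part_b, n_points=n_points)
    sasa_ab = compute_sasa(part_a + part_b, n_points=n_points)

    def dsasa(part, alone):
        out = {}
        for res in part:
            delta = alone.residue_area.get(res.key, 0.0) - sasa_ab.residue_area.get(res.key, 0.0)
            out[res.key] = delta
        return out

    da = dsasa(part_a, sasa_a)
    db = dsasa(part_b, sasa_b)
    buried = 0.5 * (sasa_a.total + sasa_b.total - sasa_ab.total)
    return InterfaceSummary(
        part_a=name_a, part_b=name_b,
        interface_residues_a=sorted(k for k, v in da.items() if v > dsasa_threshold),
        interface_residues_b=sorted(k for k, v in db.items() if v > dsasa_threshold),
        buried_area=max(buried, 0.0),
        dsasa_a=da, dsasa_b=db,
        contacts=contact_residues(part_a, part_b, cutoff=contact_cutoff),
    )


def peptide_exposed_surface(peptide: list[Residue], receptor: list[Residue],
                            n_points: int = DEFAULT_SPHERE_POINTS) -> float:
    """Exposed surface of the bound peptide: its SASA within the complex
    (= isolated accessible area minus the part buried by the receptor)."""
    if not peptide:
        raise ValueError("peptide is empty")
    if not receptor:
        return compute_sasa(peptide, n_points=n_points).total
    sasa_complex = compute_sasa(peptide + receptor, n_points=n_points)
    return float(sum(sasa_complex.residue_area.get(r.key, 0.0) for r in peptide))
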