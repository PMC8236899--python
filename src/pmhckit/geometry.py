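"""Distances, dihedrals, peptide-register geometry, and knob insertion.

The peptide-register metrics quantify how a ligand sits in the groove:

* register distances (P1-P9, P2-P9, P1-PΩ CA spans) separate the class I
  binding mode (short span, bulged middle) from the class II mode (long
  extended span) — a 9-mer bound by class I spans roughly 22 Å between P1
  and P9 while the same core in class II spans ~26 Å;
* bulge height is the maximal CA deviation from the P1→PΩ axis;
* per-register sidechain orientation (up/down/lateral) captures the class
  difference at P1: upward-pointing in class I, downward into the groove in
  class II;
* the knob-insertion score measures the fractional burial of the ia-domain
  hydrophobic knob sidechains (canonically ia56 + ia60, the β₂-m
  phenylalanine/tryptophan pair of class I) against the pab sheet floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .interfaces import compute_sasa
from .numbering import CanonicalResidueID, DomainAssignment, NumberingMap
from .structures import Residue, Structure

__all__ = [
    "DistanceMeasurement",
    "DihedralMeasurement",
    "PeptideGeometryReport",
    "KnobInsertionResult",
    "measure_distance",
    "measure_dihedral",
    "phi_psi",
    "peptide_geometry_report",
    "knob_insertion",
]

_LATERAL_BAND = 0.3  # |cos| below which an orientation is "lateral"
DEFAULT_KNOB_THRESHOLD = 0.6


@dataclass(frozen=True)
class DistanceMeasurement:
    atom_a: tuple[tuple[str, int, str | None], str]
    atom_b: tuple[tuple[str, int, str | None], str]
    value: float


@dataclass(frozen=True)
class DihedralMeasurement:
    value: float  # degrees in (-180, 180], IUPAC sign convention


@dataclass
class PeptideGeometryReport:
    register_distances: dict[str, float]
    bulge_height: float
    orientations: dict[int, str]  # register -> up | down | lateral
    terminal_exposure: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class KnobInsertionResult:
    knob_residues: list[CanonicalResidueID]
    fractional_burial: float
    inserted: bool
    per_residue: dict[str, float] = field(default_factory=dict)


def _resolve(structure: Structure, nmap: NumberingMap,
             cid: CanonicalResidueID) -> Residue:
    key = nmap.author(cid)
    if key is None:
        raise KeyError(f"canonical residue {cid} not in numbering map")
    res = structure.residue(*key)
    if res is None:
        raise KeyError(f"residue {key} absent from structure")
    return res


def measure_distance(structure: Structure, nmap: NumberingMap,
                     id_a: CanonicalResidueID, id_b: CanonicalResidueID,
                     atom: str = "CA") -> DistanceMeasurement:
    """Euclidean distance between the named atoms of two canonical residues."""
    res_a = _resolve(structure, nmap, id_a)
    res_b = _resolve(structure, nmap, id_b)
    ca = res_a.coord(atom)
    cb = res_b.coord(atom)
    if ca is None:
        raise ValueError(f"atom {atom} missing from residue {res_a!r}")
    if cb is None:
        raise ValueError(f"atom {atom} missing from residue {res_b!r}")
    return DistanceMeasurement(
        atom_a=(res_a.key, atom), atom_b=(res_b.key, atom),
        value=float(np.linalg.norm(ca - cb)),
    )


def measure_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                     p3: np.ndarray) -> DihedralMeasurement:
    """Signed dihedral p0-p1-p2-p3 in degrees, right-hand IUPAC convention."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined dihedral: three points are collinear")
    b1u = b1 / np.linalg.norm(b1)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b1u
    angle = float(np.rad2deg(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return DihedralMeasurement(value=angle)


def phi_psi(structure: Structure, chain: str) -> dict[tuple[str, int, str | None],
                                                      tuple[float | None, float | None]]:
    """Backbone (φ, ψ) per residue of one chain; None at chain termini."""
    residues = structure.chains.get(chain, [])
    out = {}
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        if n is not None and ca is not None and c is not None:
            if i > 0 and residues[i - 1].coord("C") is not None:
                phi = measure_dihedral(residues[i - 1].coord("C"), n, ca, c).value
            if i + 1 < len(residues) and residues[i + 1].coord("N") is not None:
                psi = measure_dihedral(n, ca, c, residues[i + 1].coord("N")).value
        out[res.key] = (phi, psi)
    return out


def _peptide_by_register(structure: Structure, nmap: NumberingMap):
    out = {}
    for key, cid in nmap.forward.items():
        if cid.domain_class == "peptide":
            res = structure.residue(*key)
            if res is not None:
                out[cid.register] = res
    return out


def peptide_geometry_report(structure: Structure, nmap: NumberingMap,
                            domains: DomainAssignment | None = None,
                            pomega: int | None = None) -> PeptideGeometryReport:
    """Register distances, bulge height, and per-register orientations.

    ``pomega`` names the C-terminal core register (defaults to the largest
    register that is <= 9 and present, i.e. P9 for a 9-residue core).
    Orientation uses the pab sheet-plane normal oriented toward the helices;
    |cos| < 0.3 counts as lateral.  Missing registers produce a partial
    report with warnings rather than an error.
    """
    by_reg = _peptide_by_register(structure, nmap)
    if len(by_reg) < 2:
        raise ValueError("need at least 2 registered peptide residues")
    warns: list[str] = []
    if pomega is None:
        cands = [r for r in by_reg if r is not None and r <= 9]
        pomega = max(cands) if cands else max(by_reg)

    def ca_of(reg: int):
        res = by_reg.get(reg)
        return None if res is None else res.coord("CA")

    dists: dict[str, float] = {}
    for label, (ra, rb) in (("P1-P9", (1, 9)), ("P2-P9", (2, 9)),
                            ("P1-POmega", (1, pomega))):
        a, b = ca_of(ra), ca_of(rb)
        if a is None or b is None:
            warns.append(f"register pair {label}: residue missing")
            continue
        dists[label] = float(np.linalg.norm(a - b))

    # bulge height: max CA deviation from the P1 -> POmega axis
    bulge = 0.0
    a, b = ca_of(1), ca_of(pomega)
    if a is None or b is None:
        warns.append("bulge height undefined: P1 or POmega missing")
    else:
        axis = b - a
        axis_norm = np.linalg.norm(axis)
        if axis_norm < 1e-9:
            warns.append("bulge height undefined: P1 and POmega coincide")
        else:
            axis /= axis_norm
            for reg in sorted(by_reg):
                ca = ca_of(reg)
                if ca is None or not 1 <= reg <= pomega:
                    continue
                v = ca - a
                bulge = max(bulge, float(np.linalg.norm(v - (v @ axis) * axis)))

    normal = _groove_normal(structure, nmap, domains)
    orientations: dict[int, str] = {}
    for reg, res in sorted(by_reg.items()):
        ca, cb = res.coord("CA"), res.coord("CB")
        if ca is None or cb is None:
            continue  # orientation defined only with CB present
        if normal is None:
            orientations[reg] = "undetermined"
            continue
        v = cb - ca
        c = float(v @ normal / np.linalg.norm(v))
        if abs(c) < _LATERAL_BAND:
            orientations[reg] = "lateral"
        else:
            orientations[reg] = "up" if c > 0 else "down"

    return PeptideGeometryReport(register_distances=dists, bulge_height=bulge,
                                 orientations=orientations, warnings=warns)


def _groove_normal(structure: Structure, nmap: NumberingMap,
                   domains: DomainAssignment | None) -> np.ndarray | None:
    """pab sheet-plane normal oriented toward the helices ("up")."""
    from .secondary import assign_secondary_structure, compute_backbone_hbonds

    pab_keys = {key for key, cid in nmap.forward.items()
                if cid.domain_class in ("pa", "pb")}
    if not pab_keys:
        return None
    hbonds = compute_backbone_hbonds(structure)
    ss = assign_secondary_structure(hbonds, structure)
    sheet_cas, helix_cas = [], []
    for res in structure.residues():
        if res.key not in pab_keys or res.coord("CA") is None:
            continue
        state = ss.state(res.key)
        if state == "strand":
            sheet_cas.append(res.coord("CA"))
        elif state in ("alpha", "310", "pi"):
            helix_cas.append(res.coord("CA"))
    if len(sheet_cas) < 3:
        return None
    pts = np.array(sheet_cas)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    if helix_cas:
        toward = np.mean(helix_cas, axis=0) - centroid
        if normal @ toward < 0:
            normal = -normal
    return normal


def knob_insertion(structure: Structure, nmap: NumberingMap,
                   domains: DomainAssignment,
                   knob: tuple[CanonicalResidueID, ...] | None = None,
                   target: str = "pab",
                   threshold: float = DEFAULT_KNOB_THRESHOLD,
                   n_points: int = 960) -> KnobInsertionResult:
    """Fractional burial of the ia-knob sidechains against the pab floor.

    burial = 1 − (exposed sidechain SASA in presence of the target) /
    (isolated sidechain SASA); the ``inserted`` flag applies ``threshold``
    (default 0.6) but the continuous score is always reported.  Glycine at
    a knob position has no sidechain: reported as NaN for that residue.
    """
    if knob is None:
        knob = (CanonicalResidueID("ia", 56), CanonicalResidueID("ia", 60))
    knob_res: list[Residue] = [_resolve(structure, nmap, cid) for cid in knob]
    target_res = [r for r in domains[target] if all(r.key != k.key for k in knob_res)]
    per_residue: dict[str, float] = {}
    scores = []
    for cid, res in zip(knob, knob_res):
        side = [a for a in res.heavy_atoms() if a.name not in ("N", "CA", "C", "O")]
        if not side:
            warnings.warn(f"{cid}: no sidechain atoms (glycine?); burial undefined",
                          stacklevel=2)
            per_residue[str(cid)] = float("nan")
            continue
        iso = compute_sasa([res], n_points=n_points)
        iso_side = sum(iso.atom_area[(res.key, a.name)] for a in side)
        complex_sasa = compute_sasa([res] + target_res, n_points=n_points)
        exp_side = sum(complex_sasa.atom_area[(res.key, a.name)] for a in side)
        burial = 1.0 - exp_side / iso_side if iso_side > 0 else float("nan")
        per_residue[str(cid)] = float(np.clip(burial, 0.0, 1.0))
        scores.append(per_residue[str(cid)])
    overall = float(np.mean(scores)) if scores else float("nan")
    return KnobInsertionResult(
        knob_residues=list(knob),
        fractional_burial=overall,
        inserted=bool(overall >= threshold) if scores else False,
        per_residue=per_residue,
    )
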