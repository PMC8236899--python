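"""Synthetic structure and alignment generators with known ground truth.

Every pipeline stage in this package is testable offline against fixtures
built here: ideal α/3₁₀/π helices, flat antiparallel β-sheets with optional
engineered two-residue bulges, and toy peptide-groove complexes that mimic
the pMHC architecture (an eight-strand β-sheet floor, two antiparallel
helical walls, a registered peptide lying in the groove, and IgSF-like
appendages).  The toys are geometric caricatures, not homology models: they
exist to give the detectors answers that are known by construction.

Backbones are grown atom-by-atom with the standard internal-coordinate
(NeRF) construction from ideal bond lengths and angles, so dihedral
measurements recover the requested φ/ψ exactly and hydrogen-bond patterns
follow from the geometry rather than from any annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .numbering import CanonicalResidueID, NumberingMap
from .structures import Atom, Residue, Structure

__all__ = [
    "HelixSpec",
    "SheetSpec",
    "ToyComplexSpec",
    "make_ideal_helix",
    "make_beta_sheet",
    "make_toy_pmhc",
    "make_toy_alignment",
    "HELIX_DIHEDRALS",
]

# Ideal backbone internal coordinates (Engh–Huber-like), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0

#: Canonical (φ, ψ) in degrees per helix kind.
HELIX_DIHEDRALS = {"alpha": (-57.0, -47.0), "310": (-49.0, -26.0), "pi": (-57.0, -70.0)}
_HELIX_MIN_LENGTH = {"alpha": 4, "310": 3, "pi": 5}

#: Repeating (φ, ψ) used for strands; near the ideal antiparallel β region.
STRAND_PHI_PSI = (-139.0, 135.0)

# Toy-complex layout constants (Å): wall helix axis placement relative to
# the groove midline/sheet plane, and knob pseudo-sidechain geometry.
WALL_Y_OFFSET = 6.2
WALL_Z = 6.6
KNOB_TIP_OVERSHOOT = 0.2
KNOB_TIP_JITTER = 0.1

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position D bonded to C, given A-B-C and internal coords."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]],
                   sequence: str | None = None,
                   with_cb: bool = True) -> list[dict[str, np.ndarray]]:
    """Grow a poly-peptide backbone from per-residue (φ, ψ), ω = 180°.

    φ of the first residue and ψ of the last are irrelevant to the chain
    but are consumed for uniformity.  Returns one dict of atom coordinates
    per residue with keys N, CA, C, O (and CB unless glycine/with_cb=False).
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    seq = sequence or "A" * n_res
    residues: list[dict[str, np.ndarray]] = []
    # Seed frame for residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # Carbonyl O: trans to the next N across the C; last O from ψ convention.
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            nxt = residues[i + 1]["N"]
            res["O"] = _place_atom(nxt, res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O,
                                   180.0)
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], BOND_C_O,
                                   ANGLE_CA_C_O, phi_psi[i][1] + 180.0)
        if with_cb and _AA3.get(seq[i], "ALA") != "GLY":
            # L-configuration Cβ from the improper N-C-CA-CB torsion.
            res["CB"] = _place_atom(res["N"], res["C"], res["CA"], BOND_CA_CB,
                                    ANGLE_N_CA_CB, 122.6)
    return residues


def _o_torsion_fix(residues: list[dict[str, np.ndarray]]) -> None:
    """Re-place O atoms trans to the following amide N (planar peptide bond)."""
    for i in range(len(residues) - 1):
        res, nxt = residues[i], residues[i + 1]
        # O lies in the CA-C-N(i+1) plane, opposite N(i+1)
        c, ca, n_next = res["C"], res["CA"], nxt["N"]
        v1 = ca - c
        v2 = n_next - c
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        bisec = v1 + v2
        bisec /= np.linalg.norm(bisec)
        res["O"] = c - BOND_C_O * bisec


def _to_structure(chains: dict[str, list[tuple[int, str, dict[str, np.ndarray]]]],
                  structure_id: str) -> Structure:
    st = Structure(id=structure_id)
    for chain_id, entries in chains.items():
        st.chains[chain_id] = [
            Residue(
                author_chain=chain_id,
                author_seqnum=num,
                author_icode=None,
                resname=resname,
                atoms=[Atom(name, _element_of(name), xyz) for name, xyz in atom_map.items()],
            )
            for num, resname, atom_map in entries
        ]
    return st


def _element_of(atom_name: str) -> str:
    return atom_name[0]


@dataclass
class HelixSpec:
    n_residues: int
    kind: str = "alpha"  # alpha | 310 | pi
    phi: float | None = None
    psi: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in HELIX_DIHEDRALS:
            raise ValueError(f"unknown helix kind {self.kind!r}")
        if self.n_residues < _HELIX_MIN_LENGTH[self.kind]:
            raise ValueError(
                f"{self.kind} helix needs >= {_HELIX_MIN_LENGTH[self.kind]} residues"
            )
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def make_ideal_helix(spec: HelixSpec | int, kind: str = "alpha") -> Structure:
    """Poly-alanine helix with exact canonical φ/ψ for the requested kind."""
    if isinstance(spec, int):
        spec = HelixSpec(n_residues=spec, kind=kind)
    phi0, psi0 = HELIX_DIHEDRALS[spec.kind]
    phi = spec.phi if spec.phi is not None else phi0
    psi = spec.psi if spec.psi is not None else psi0
    residues = build_backbone([(phi, psi)] * spec.n_residues, spec.sequence)
    _o_torsion_fix(residues)
    seq = spec.sequence or "A" * spec.n_residues
    entries = [(i + 1, _AA3.get(seq[i], "ALA"), residues[i]) for i in range(spec.n_residues)]
    return _to_structure({"A": entries}, f"helix-{spec.kind}-{spec.n_residues}")


# ---------------------------------------------------------------------------
# Antiparallel β-sheets
# ---------------------------------------------------------------------------

@dataclass
class SheetSpec:
    n_strands: int = 2
    strand_length: int = 6
    sense: str = "antiparallel"
    bulge_at: tuple[int, int] | None = None  # (strand index, residue position 1-based)

    def __post_init__(self) -> None:
        if self.sense != "antiparallel":
            raise ValueError("only antiparallel sheets are generated")
        if self.strand_length < 3:
            raise ValueError("strand_length must be >= 3")
        if self.n_strands < 1:
            raise ValueError("n_strands must be >= 1")
        if self.bulge_at is not None:
            s, k = self.bulge_at
            if not 0 <= s < self.n_strands:
                raise ValueError("bulge strand index out of range")
            lo, hi = self.valid_bulge_slots()
            if not lo <= k <= hi:
                raise ValueError(
                    f"bulge slot must lie in [{lo}, {hi}] so both flanking "
                    "ladder rungs can form"
                )

    def valid_bulge_slots(self) -> tuple[int, int]:
        """Inclusive slot range where an engineered bulge keeps both
        flanking rungs away from strand termini."""
        reg = _sheet_register(self.strand_length)
        return 2 + reg, self.strand_length - 3


def _twofold_strand_psi(phi: float) -> float:
    """ψ making the repeating (φ, ψ) conformation an exact 2₁ screw.

    A strand whose per-residue screw rotation is exactly 180° is flat and
    untwisted, which lets long ideal ladders be built by symmetry.
    """

    def defect(psi: float) -> float:
        res = build_backbone([(phi, float(psi))] * 6, with_cb=False)
        # per-residue transform from residue frames 1 -> 3 (two steps = 360°)
        a = np.array([res[1]["N"], res[1]["CA"], res[1]["C"]])
        b = np.array([res[3]["N"], res[3]["CA"], res[3]["C"]])
        # rotation angle of the two-residue step should be 0 (mod 360)
        R, _ = _rigid_from_pairs(a, b)
        ang = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        return ang

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(defect, bounds=(120.0, 160.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _rigid_from_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping point set a onto b (local helper)."""
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca_).T @ (b - cb_)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cb_ - R @ ca_


_SHEET_CACHE: dict[str, object] = {}


def _ideal_strand(n: int) -> list[dict[str, np.ndarray]]:
    """Flat 2₁ strand of n alanines, axis-aligned along +x, centred at origin."""
    key = f"psi:{STRAND_PHI_PSI[0]}"
    if key not in _SHEET_CACHE:
        _SHEET_CACHE[key] = _twofold_strand_psi(STRAND_PHI_PSI[0])
    psi = _SHEET_CACHE[key]
    residues = build_backbone([(STRAND_PHI_PSI[0], psi)] * n)
    _o_torsion_fix(residues)
    # Align the strand axis (CA(i) -> CA(i+2)) with +x, CAs near the xz plane.
    cas = np.array([r["CA"] for r in residues])
    axis = cas[2] - cas[0]
    axis /= np.linalg.norm(axis)
    # pleat direction: component of CA(1) off the axis line through CA(0)
    mid = (cas[0] + cas[2]) / 2
    pleat = cas[1] - mid
    pleat -= axis * (pleat @ axis)
    pleat /= np.linalg.norm(pleat)
    ex, ez = axis, pleat
    ey = np.cross(ez, ex)
    R = np.array([ex, ey, ez])  # rows: new basis
    centre = cas.mean(axis=0)
    out = []
    for r in residues:
        out.append({k: R @ (v - centre) for k, v in r.items()})
    return out


def _mirror_strand(strand: list[dict[str, np.ndarray]],
                   shift: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Antiparallel partner: 180° rotation about z through the origin, then shift."""
    Rz = np.diag([-1.0, -1.0, 1.0])
    return [{k: Rz @ v + shift for k, v in r.items()} for r in strand]


def _optimal_sheet_shift(n: int) -> np.ndarray:
    """Rigid offset of the antiparallel partner strand placing the canonical
    narrow-pair N···O hydrogen bonds at 2.9 Å, solved once and cached.

    The intended register pairs residue i (0-based) of strand A with residue
    n-1-i of the mirrored strand B; narrow pairs (both N-H···O=C bonds inside
    the pair) sit at alternate rungs, wide pairs follow by the 2₁ symmetry
    of the strand conformation.
    """
    key = f"shift:{n}"
    if key in _SHEET_CACHE:
        return _SHEET_CACHE[key]  # type: ignore[return-value]
    strand_a = _ideal_strand(n)
    register = _sheet_register(n)

    def narrow_defect(params: np.ndarray, parity: int) -> float:
        strand_b = _mirror_strand(strand_a, np.asarray(params, float))
        total = 0.0
        count = 0
        for i in range(n):
            j = n - 1 - i + register
            if i % 2 != parity or not 0 <= j < n:
                continue
            d1 = np.linalg.norm(strand_a[i]["N"] - strand_b[j]["O"])
            d2 = np.linalg.norm(strand_b[j]["N"] - strand_a[i]["O"])
            total += (d1 - 2.9) ** 2 + (d2 - 2.9) ** 2
            count += 1
        return total / max(count, 1)

    # bounds keep the partner in the physical inter-strand range (~4.8 Å)
    bounds = [(-3.4, 3.4), (4.2, 5.6), (-1.0, 1.0)]
    best = None
    for parity in (0, 1):
        for dx0 in np.arange(-2.0, 2.1, 1.0):
            res = minimize(narrow_defect, np.array([dx0, 4.8, 0.0]), args=(parity,),
                           method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    _SHEET_CACHE[key] = best.x.copy()
    return best.x


def _sheet_register(n: int) -> int:
    """Partner-strand register offset: residue i pairs with n-1-i+register.

    The 2₁ strand alternates the facing of N-H/C=O along the sequence; a
    narrow pair needs both partners facing each other, which fixes the
    register parity: 0 for odd strand lengths, 1 for even."""
    return 1 if n % 2 == 0 else 0


@dataclass
class SheetGroundTruth:
    """Construction annotations for a synthetic sheet.

    ``paired_positions`` lists every template rung; ``interior_pairs`` the
    subset whose residues all have chain neighbours on both sides (the rungs
    the bridge patterns, which reference i±1/j±1, are able to report).
    """

    paired_positions: list[tuple[tuple[str, int], tuple[str, int]]]
    interior_pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    strand_lengths: dict[str, int] = field(default_factory=dict)
    #: key of the inserted (arcing) residue; a detected bulge pair must
    #: contain it and stay within ``bulge_window``
    bulge_inserted: tuple[str, int] | None = None
    bulge_window: tuple[tuple[str, int], ...] = ()
    bulge_opposite_window: tuple[tuple[str, int], ...] = ()


def make_beta_sheet(spec: SheetSpec | None = None, **kwargs) -> tuple[Structure, SheetGroundTruth]:
    """Idealized flat antiparallel β-sheet, one chain per strand (A, B, ...).

    Without a bulge every residue i of strand s pairs with residue
    (L + 1 - i) of strand s+1.  With ``bulge_at=(s, k)`` strand s receives a
    two-residue insertion after its k-th template slot: the two inserted-
    plus-shifted residues oppose a single partner residue, flanked by
    regular pairs, and both bulge sidechains point to the same face —
    the classic β-bulge that the detector must find.
    """
    if spec is None:
        spec = SheetSpec(**kwargs)
    L = spec.strand_length
    shift = _optimal_sheet_shift(L)
    base = _ideal_strand(L)

    chains: dict[str, list[tuple[int, str, dict[str, np.ndarray]]]] = {}
    truth_pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    strand_coords: list[list[dict[str, np.ndarray]]] = []
    for s in range(spec.n_strands):
        if s % 2 == 0:
            coords = [{k: v + np.array([0.0, s * shift[1], 0.0]) for k, v in r.items()}
                      for r in base]
        else:
            sh = shift + np.array([0.0, (s - 1) * shift[1], 0.0])
            coords = _mirror_strand(base, sh)  # runs -x; list order stays N->C
        strand_coords.append(coords)

    bulged = None
    if spec.bulge_at is not None:
        s_idx, k = spec.bulge_at
        strand_coords[s_idx] = _insert_bulge(strand_coords[s_idx], k)
        bulged = (s_idx, k)

    chain_ids = [chr(ord("A") + s) for s in range(spec.n_strands)]
    for s, coords in enumerate(strand_coords):
        chains[chain_ids[s]] = [(i + 1, "ALA", coords[i]) for i in range(len(coords))]

    # ground-truth pairing: template slot t of strand s pairs with slot
    # (L + 1 - t + register) of strand s+1 (1-based; antiparallel).
    reg = _sheet_register(L)

    def slot_to_resnum(s: int, t: int) -> int | None:
        if bulged is not None and s == bulged[0]:
            k = bulged[1]
            return t if t <= k else t + 1  # one extra residue inserted after slot k
        return t

    for s in range(spec.n_strands - 1):
        for t in range(1, L + 1):
            partner = L + 1 - t + reg
            if not 1 <= partner <= L:
                continue
            ra = slot_to_resnum(s, t)
            rb = slot_to_resnum(s + 1, partner)
            if ra is not None and rb is not None:
                truth_pairs.append(((chain_ids[s], ra), (chain_ids[s + 1], rb)))

    lengths = {chain_ids[s]: len(strand_coords[s]) for s in range(spec.n_strands)}
    interior = [
        ((ca_, ra), (cb_, rb))
        for (ca_, ra), (cb_, rb) in truth_pairs
        if 2 <= ra <= lengths[ca_] - 1 and 2 <= rb <= lengths[cb_] - 1
    ]
    truth = SheetGroundTruth(paired_positions=truth_pairs, interior_pairs=interior,
                             strand_lengths=lengths)
    if bulged is not None:
        s_idx, k = bulged
        cid = chain_ids[s_idx]
        truth.bulge_inserted = (cid, k + 1)
        truth.bulge_window = ((cid, k), (cid, k + 1), (cid, k + 2))
        opp_strand = s_idx + 1 if s_idx + 1 < spec.n_strands else s_idx - 1
        opp_cid = chain_ids[opp_strand]
        centre = L - k + reg
        truth.bulge_opposite_window = tuple((opp_cid, centre + d) for d in (-1, 0, 1))
    st = _to_structure(chains, "sheet")
    return st, truth


def _insert_bulge(coords: list[dict[str, np.ndarray]], k: int) -> list[dict[str, np.ndarray]]:
    """Insert one extra residue after template slot k (1-based).

    The inserted residue and its successor form the bulge pair: they are
    lifted off the sheet plane and compressed along the strand axis so both
    Cβ point to the same face, while residues before slot k and after slot
    k+1 keep their regular template geometry and hydrogen bonds.
    """
    out = [dict(r) for r in coords[:k]]
    a = coords[k - 1]   # slot k (last regular residue before the extra one)
    b = coords[k]       # slot k+1; keeps its template geometry and H-bonds
    # One extra residue arcing above the sheet plane between slots k and
    # k+1, with real peptide bonds (~1.33 Å) to both neighbours; it forms no
    # ladder H-bonds of its own, so the partner strand advances one position
    # while this strand advances two — the classic bulge.
    up = np.array([0.0, 0.0, 1.0])
    along = b["N"] - a["C"]
    along /= np.linalg.norm(along)
    extra: dict[str, np.ndarray] = {}
    extra["N"] = a["C"] + 1.33 * (0.35 * along + 0.94 * up)
    extra["C"] = b["N"] + 1.33 * (-0.35 * along + 0.94 * up)
    mid = (extra["N"] + extra["C"]) / 2
    extra["CA"] = mid + 1.30 * up
    # carbonyl O points sideways off the arc, away from the partner strands
    side = np.cross(up, along)
    extra["O"] = extra["C"] + 1.23 * (0.80 * side + 0.60 * up)
    follower = {key: v.copy() for key, v in b.items()}
    # every sidechain in the bulge window points up, off the sheet plane
    out[k - 1]["CB"] = out[k - 1]["CA"] + np.array([0.0, 0.0, 1.53])
    extra["CB"] = extra["CA"] + np.array([0.0, 0.0, 1.53])
    follower["CB"] = follower["CA"] + np.array([0.0, 0.0, 1.53])
    out.append(extra)
    out.append(follower)
    out.extend(dict(r) for r in coords[k + 1:])
    return out


# ---------------------------------------------------------------------------
# Toy pMHC complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    class_type: str = "II"          # "I" or "II"
    strand_length: int = 9
    peptide_length: int = 9         # registered core is always P1..P9
    peptide_overhang: int = 0       # extra residues beyond each groove end
    peptide_height: float = 5.2     # Å above the sheet plane
    peptide_bulge: float | None = None  # arc height, Å; default 6.0 (I) / 0 (II)
    ib_hinge_angle: float = 0.0     # degrees; rotation of the ib appendage
    with_knob: bool | None = None   # default: True for class I, False for II
    with_cleft: bool = True         # engineer the class-typical S2-S3 cleft
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_type not in ("I", "II"):
            raise ValueError("class_type must be 'I' or 'II'")
        if self.peptide_length < 2:
            raise ValueError("peptide must have at least 2 residues")
        if self.strand_length % 2 == 0 or self.strand_length < 9:
            raise ValueError("toy floor strands must have odd length >= 9")
        if self.with_knob is None:
            self.with_knob = self.class_type == "I"
        if self.peptide_bulge is None:
            # class I binds the 9-mer core non-relaxed: the chain arcs out
            # of the groove, shortening the P1-P9 span by ~15% as observed
            # between real class I and class II 9-mer cores
            self.peptide_bulge = 6.0 if self.class_type == "I" else 0.0
        if self.class_type == "I" and self.peptide_overhang:
            raise ValueError("class I toys have closed groove ends (no overhang)")


@dataclass
class ToyGroundTruth:
    """Construction facts the pipeline must recover from the coordinates."""

    contacts: set = field(default_factory=set)
    p1_key: tuple | None = None
    pomega_key: tuple | None = None
    hinge_angle: float = 0.0
    knob_keys: list = field(default_factory=list)
    knob_inserted: bool = False
    peptide_bulge: float = 0.0
    peptide_span: float = 0.0       # construction P1..P9 CA distance, Å
    cleft_domain: str | None = None  # domain engineered with the S2-S3 cleft
    expected_orientations: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "contacts": sorted([[list(a), list(b)] for a, b in self.contacts]),
            "p1_key": list(self.p1_key) if self.p1_key else None,
            "pomega_key": list(self.pomega_key) if self.pomega_key else None,
            "hinge_angle": self.hinge_angle,
            "knob_keys": [list(k) for k in self.knob_keys],
            "knob_inserted": self.knob_inserted,
            "peptide_bulge": self.peptide_bulge,
            "peptide_span": self.peptide_span,
            "cleft_domain": self.cleft_domain,
            "expected_orientations": {str(k): v for k, v in
                                      self.expected_orientations.items()},
        }, indent=1)


def make_toy_pmhc(spec: ToyComplexSpec | None = None, **kwargs):
    """Toy peptide-groove complex with construction ground truth.

    Returns ``(structure, numbering_map, ground_truth)``.

    Architecture (one frame; the sheet plane is z = 0, strands run +x):

    * chain A — eight-strand antiparallel floor (strands S1-S4 of pa then
      S1-S4 of pb) plus two wall helices above it (one per domain); the
      class-typical S2-S3 cleft is engineered by bending the outer end of
      the cleft domain's S3 strand off the sheet so its outermost surviving
      main-chain pairing is the canonical p24-p36 rung, while the intact
      domain pairs out to p22-p38;
    * chain C — the peptide, extended, in the groove between the walls;
      class I closes the groove (long walls, no overhang, optional bulge
      and P1-up/PΩ-down sidechains), class II leaves the ends open
      (overhang allowed, P1 and P9 sidechains down);
    * chain B — an ia-like strand under the floor; class I toys point two
      long hydrophobic pseudo-sidechains (canonical ia56 + ia60) up into
      floor gaps — the knob; class II toys keep plain short sidechains;
    * chain D — an ib-like helical appendage hinged by ``ib_hinge_angle``
      about the groove axis.
    """
    if spec is None:
        spec = ToyComplexSpec(**kwargs)
    L = spec.strand_length
    sheet_spec = SheetSpec(n_strands=8, strand_length=L)
    sheet, _ = make_beta_sheet(sheet_spec)
    dy = float(_optimal_sheet_shift(L)[1])
    strand_coords = [
        [{a.name: a.coords.copy() for a in res.atoms} for res in sheet.chains[cid]]
        for cid in (chr(ord("A") + i) for i in range(8))
    ]

    narrow_t = _narrow_rung_slot(L)
    # cleft domain per class: pb for class I complexes, pa for class II
    cleft_domain = ("pb" if spec.class_type == "I" else "pa") if spec.with_cleft else None
    # canonical starts per strand (S1, S2, S3, S4); the cleft domain's
    # S2/S3 starts are chosen so its outermost *surviving* narrow rung is
    # exactly the p24-p36 pair
    default_starts = (1, 21, 31, 51)
    starts = {"pa": list(default_starts), "pb": list(default_starts)}
    if cleft_domain is not None:
        starts[cleft_domain][1] = 24 - (narrow_t - 1)
        starts[cleft_domain][2] = 36 - (L - narrow_t)
        s3_idx = 2 if cleft_domain == "pa" else 6
        keep_slots = L + 1 - narrow_t  # S3 slots 1..keep_slots stay in plane
        for rank, slot in enumerate(range(keep_slots + 1, L + 1), start=1):
            # bend away from the sheet on the non-groove side (downward)
            lift = np.array([0.0, 0.0, -1.6 * rank])
            for name in strand_coords[s3_idx][slot - 1]:
                strand_coords[s3_idx][slot - 1][name] = (
                    strand_coords[s3_idx][slot - 1][name] + lift
                )

    chains: dict[str, list[tuple[int, str, dict[str, np.ndarray]]]] = {"A": []}
    strand_keys: list[list[int]] = []
    for s, coords in enumerate(strand_coords):
        nums = []
        for i, atom_map in enumerate(coords):
            num = s * 100 + i + 1
            chains["A"].append((num, "ALA", atom_map))
            nums.append(num)
        strand_keys.append(nums)

    sheet_y = 7 * dy
    groove_mid_y = sheet_y / 2
    strand_span = (L - 1) * 3.34
    centre_x = float(np.mean([r["CA"][0] for r in strand_coords[0]]))

    # Wall helices along x above the floor; class I walls are long enough
    # to enclose the peptide termini, class II walls stop short of them.
    pep_core_span = (spec.peptide_length - 1) * 3.34
    if spec.class_type == "I":
        helix_len = int(np.ceil(pep_core_span / 1.5)) + 4
    else:
        helix_len = max(8, int(np.ceil((pep_core_span - 8.0) / 1.5)))
    wall_a = _helix_along_x(helix_len, y=groove_mid_y - WALL_Y_OFFSET, z=WALL_Z,
                            centre_x=centre_x)
    wall_b = _helix_along_x(helix_len, y=groove_mid_y + WALL_Y_OFFSET, z=WALL_Z,
                            centre_x=centre_x)
    for i, r in enumerate(wall_a):
        chains["A"].append((900 + i + 1, "ALA", r))
    for i, r in enumerate(wall_b):
        chains["A"].append((1000 + i + 1, "ALA", r))

    # Peptide: extended strand along x, centred in the groove.
    pep_total = spec.peptide_length + 2 * spec.peptide_overhang
    pep = _ideal_strand(pep_total)
    pep_centre = float(np.mean([r["CA"][0] for r in pep]))
    pep_shift = np.array([centre_x - pep_centre, groove_mid_y, spec.peptide_height])
    pep = [{k: v + pep_shift for k, v in r.items()} for r in pep]
    # P1/P9 sidechain engineering: class II both down (the ancestral,
    # symmetric mode); class I P1 up, PΩ down.
    i_p1 = spec.peptide_overhang
    i_pw = spec.peptide_overhang + spec.peptide_length - 1
    down = np.array([0.0, 0.0, -1.53])
    if spec.class_type == "II":
        pep[i_p1]["CB"] = pep[i_p1]["CA"] + down
        pep[i_pw]["CB"] = pep[i_pw]["CA"] + down
        expected_orient = {1: "down", spec.peptide_length: "down"}
    else:
        pep[i_p1]["CB"] = pep[i_p1]["CA"] - down
        pep[i_pw]["CB"] = pep[i_pw]["CA"] + down
        expected_orient = {1: "up", spec.peptide_length: "down"}
    if spec.peptide_bulge > 0:
        pep = _bend_into_arc(pep, spec.peptide_bulge)
    chains["C"] = [(i + 1, "ALA", pep[i]) for i in range(pep_total)]
    p1_ca = pep[i_p1]["CA"].copy()
    pw_ca = pep[i_pw]["CA"].copy()

    # ia-like strand below the floor; knob sidechains for class I.
    ia = _ideal_strand(8)
    ia_centre = float(np.mean([r["CA"][0] for r in ia]))
    # class I ia sits close enough for its knob to reach into the floor;
    # class II ia keeps backbone contact but its short sidechains stay out
    ia_depth = -6.0 if spec.class_type == "I" else -8.5
    ia_shift = np.array([centre_x - ia_centre, groove_mid_y, ia_depth])
    ia = [{k: v + ia_shift for k, v in r.items()} for r in ia]
    ia_entries = []
    knob_truth_keys = []
    for i, r in enumerate(ia):
        resname = "ALA"
        if spec.with_knob and i in (3, 7):
            resname = "PHE" if i == 3 else "TRP"
            r = dict(r)
            r.update(_best_knob_sidechain(strand_coords, r["CA"], dy=dy))
            knob_truth_keys.append(("B", i + 1, None))
        ia_entries.append((i + 1, resname, r))
    chains["B"] = ia_entries

    # ib-like appendage hinged about the groove axis at the pb edge.
    ib = _helix_along_x(8, y=sheet_y + 6.0, z=-4.0, centre_x=centre_x)
    hinge = np.deg2rad(spec.ib_hinge_angle)
    Rx = np.array([[1, 0, 0],
                   [0, np.cos(hinge), -np.sin(hinge)],
                   [0, np.sin(hinge), np.cos(hinge)]])
    pivot = np.array([centre_x, sheet_y, 0.0])
    ib = [{k: Rx @ (v - pivot) + pivot for k, v in r.items()} for r in ib]
    chains["D"] = [(i + 1, "ALA", ib[i]) for i in range(len(ib))]

    st = _to_structure(chains, f"toy-pmhc-{spec.class_type}")
    nmap = _toy_numbering(spec, strand_keys, starts, helix_len, pep_total)
    truth = _toy_ground_truth(st, nmap, spec)
    truth.cleft_domain = cleft_domain
    truth.knob_keys = knob_truth_keys
    truth.knob_inserted = bool(knob_truth_keys)
    truth.expected_orientations = expected_orient
    truth.peptide_span = float(np.linalg.norm(p1_ca - pw_ca))
    # construction oracle for bulge height: max CA deviation from the
    # P1 -> POmega axis, computed directly from the build coordinates
    axis = pw_ca - p1_ca
    axis = axis / np.linalg.norm(axis)
    dev = 0.0
    for i in range(i_p1, i_pw + 1):
        v = pep[i]["CA"] - p1_ca
        dev = max(dev, float(np.linalg.norm(v - (v @ axis) * axis)))
    truth.peptide_bulge = dev
    return st, nmap, truth


def _narrow_rung_slot(L: int) -> int:
    """Template slot t nearest the S2 centre whose rung is a narrow pair.

    Found once per strand length by building a two-strand sheet and testing
    for the double (mutual N-H···O=C) hydrogen bond; cached.
    """
    key = f"narrow:{L}"
    if key in _SHEET_CACHE:
        return _SHEET_CACHE[key]  # type: ignore[return-value]
    from .secondary import compute_backbone_hbonds

    # measured on the middle pair of a 3-strand sheet: the toy floor uses
    # S2/S3 = strands at odd/even sheet positions, whose narrow-pair phase
    # differs from the first pair
    st, _ = make_beta_sheet(SheetSpec(n_strands=3, strand_length=L))
    bonds = {(b.donor[:2], b.acceptor[:2]) for b in compute_backbone_hbonds(st)}
    reg = _sheet_register(L)
    narrow = []
    for t in range(2, L - 1):
        partner = L + 1 - t + reg
        if not 2 <= partner <= L - 1:
            continue
        a, b = ("B", t), ("C", partner)
        if (a, b) in bonds and (b, a) in bonds:
            narrow.append(t)
    # t >= 4 keeps the renumbered S2/S3 canonical ranges disjoint
    narrow = [t for t in narrow if t >= 4]
    if not narrow:  # pragma: no cover - construction guarantee
        raise RuntimeError("no usable narrow rung found in template sheet")
    best = min(narrow, key=lambda t: abs(t - 4))
    _SHEET_CACHE[key] = best
    return best


def _best_knob_sidechain(strand_coords, ca: np.ndarray, dy: float) -> dict[str, np.ndarray]:
    """Pseudo-sidechain from ``ca`` into the sheet-plane opening that keeps
    every sidechain atom maximally clear of the floor atoms.

    Candidate openings sit between strand rows (the sheet midline and one
    row spacing to either side) near the residue's x position; the winning
    candidate maximizes the minimum atom-to-floor distance of the actual
    placed sidechain."""
    floor = np.array([v for coords in strand_coords for r in coords
                      for v in r.values()])
    y_mid = float(np.mean(floor[:, 1]))
    xs = np.arange(ca[0] - 3.5, ca[0] + 3.6, 0.25)
    best, best_clear = None, -1.0
    for x in xs:
        for y in (y_mid, y_mid - dy, y_mid + dy):
            tip = np.array([x, y, 0.2])
            side = _pseudo_sidechain(ca, tip)
            pts = np.array(list(side.values()))
            clear = float(min(np.min(np.linalg.norm(floor - p, axis=1))
                              for p in pts))
            if clear > best_clear:
                best, best_clear = side, clear
    return best


def _pseudo_sidechain(ca: np.ndarray, tip: np.ndarray) -> dict[str, np.ndarray]:
    """Aromatic-sized pseudo-sidechain from CA toward (and slightly past)
    the floor-gap tip, atoms spaced ~1.45 Å."""
    v = tip - ca
    length = np.linalg.norm(v)
    v = v / length
    names = ("CB", "CG", "CD1", "CD2", "CE1")
    # distribute atoms from 1.52 Å out of CA up to just past the tip
    ds = np.linspace(1.52, length + KNOB_TIP_OVERSHOOT, len(names))
    out = {}
    lateral = np.cross(v, [1.0, 0.0, 0.0])
    if np.linalg.norm(lateral) < 1e-6:
        lateral = np.cross(v, [0.0, 1.0, 0.0])
    lateral /= np.linalg.norm(lateral)
    for i, (name, d) in enumerate(zip(names, ds)):
        jitter = KNOB_TIP_JITTER * lateral if name in ("CD2", "CE1") else 0.0
        out[name] = ca + d * v + (jitter if isinstance(jitter, np.ndarray) else 0.0)
    return out


def _bend_into_arc(pep: list[dict[str, np.ndarray]], sagitta: float) -> list[dict[str, np.ndarray]]:
    """Bend an extended chain into a circular arc in the xz plane.

    Arc length equals the original chain span, so local geometry is nearly
    preserved; the apex rises ``sagitta`` Å and the end-to-end distance
    (the chord) shortens accordingly — the class I binding mode.
    """
    from scipy.optimize import brentq

    cas = np.array([r["CA"] for r in pep])
    x0 = cas[:, 0].mean()
    arc_len = cas[-1][0] - cas[0][0]
    if arc_len <= 0 or sagitta <= 0:
        return pep

    def defect(theta: float) -> float:
        return (arc_len / theta) * (1.0 - np.cos(theta / 2.0)) - sagitta

    theta = brentq(defect, 1e-6, 1.9 * np.pi, xtol=1e-12)
    radius = arc_len / theta
    out = []
    for r in pep:
        ca = r["CA"]
        s_arc = ca[0] - x0
        phi = s_arc / radius
        Ry = np.array([[np.cos(phi), 0.0, np.sin(phi)],
                       [0.0, 1.0, 0.0],
                       [-np.sin(phi), 0.0, np.cos(phi)]])
        target = np.array([x0 + radius * np.sin(phi), ca[1],
                           ca[2] + radius * np.cos(phi) - radius * np.cos(theta / 2.0)])
        out.append({k: Ry @ (v - ca) + target + (v - ca) * 0.0 for k, v in r.items()})
    return out


def _helix_along_x(n: int, y: float, z: float, centre_x: float = 0.0) -> list[dict[str, np.ndarray]]:
    """Poly-glycine α-helix with its axis along +x at the given (y, z)."""
    helix = make_ideal_helix(HelixSpec(n_residues=n, kind="alpha", sequence="G" * n))
    coords = [{a.name: a.coords.copy() for a in r.atoms} for r in helix.chains["A"]]
    cas = np.array([r["CA"] for r in coords])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    ex = axis
    ref = np.array([0.0, 0.0, 1.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.array([ex, ey, ez])
    centre = cas.mean(axis=0)
    return [{k: R @ (v - centre) + np.array([centre_x, y, z]) for k, v in r.items()}
            for r in coords]


def _toy_numbering(spec: ToyComplexSpec, strand_keys, starts,
                   helix_len: int, pep_total: int) -> NumberingMap:
    """Canonical numbering: pa = strands 0-3 + wall A, pb = strands 4-7 +
    wall B, ia = chain B (positions 53-60), ib = chain D, peptide = chain C
    with P1 after the overhang."""
    class_label = "MHC-I" if spec.class_type == "I" else "MHC-II"
    nmap = NumberingMap(class_label=class_label)
    for s, nums in enumerate(strand_keys):
        domain = "pa" if s < 4 else "pb"
        start = starts[domain][s % 4]
        for off, num in enumerate(nums):
            nmap.add(("A", num, None), CanonicalResidueID(domain, start + off))
    for i in range(helix_len):
        nmap.add(("A", 900 + i + 1, None), CanonicalResidueID("pa", 61 + i))
        nmap.add(("A", 1000 + i + 1, None), CanonicalResidueID("pb", 61 + i))
    for i in range(8):
        nmap.add(("B", i + 1, None), CanonicalResidueID("ia", 53 + i))
    for i in range(8):
        nmap.add(("D", i + 1, None), CanonicalResidueID("ib", i + 1))
    for i in range(pep_total):
        register = i + 1 - spec.peptide_overhang
        nmap.add(("C", i + 1, None), CanonicalResidueID("peptide", 1, register=register))
    return nmap


def _toy_ground_truth(st: Structure, nmap: NumberingMap,
                      spec: ToyComplexSpec) -> ToyGroundTruth:
    truth = ToyGroundTruth(hinge_angle=spec.ib_hinge_angle,
                           peptide_bulge=spec.peptide_bulge)
    pep = st.chains["C"]
    others = [r for cid in ("A", "B", "D") for r in st.chains[cid]]
    # exhaustive O(n^2) atom-pair scan at build time: the stored truth that
    # the fast contact search must reproduce
    for pr in pep:
        for orr in others:
            dmin = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in pr.heavy_atoms() for b in orr.heavy_atoms()
            )
            if dmin <= 4.0:
                truth.contacts.add((pr.key, orr.key))
    for res in pep:
        cid = nmap.canonical(res.key)
        if cid and cid.register == 1:
            truth.p1_key = res.key
        if cid and cid.register == spec.peptide_length:
            truth.pomega_key = res.key
    return truth


# ---------------------------------------------------------------------------
# Toy alignments
# ---------------------------------------------------------------------------

def make_toy_alignment(n_sequences: int = 6, n_columns: int = 40, seed: int = 0,
                       identity: float | None = None):
    """Random gapped alignment with hand-countable ground truth.

    Returns ``(records, truth)`` where records is a list of (name, gapped
    sequence) and truth maps ordered sequence-name pairs to the exact
    (matches, shared non-gap columns) counts used by the identity oracle.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.choice(alphabet, size=n_columns)
    records = []
    for i in range(n_sequences):
        seq = base.copy()
        mutate = rng.random(n_columns) < (0.3 if identity is None else 1 - identity)
        seq[mutate] = rng.choice(alphabet, size=int(mutate.sum()))
        gaps = rng.random(n_columns) < 0.08
        seq = np.where(gaps, "-", seq)
        records.append((f"seq{i}", "".join(seq)))
    truth = {}
    for i in range(n_sequences):
        for j in range(n_sequences):
            si, sj = records[i][1], records[j][1]
            shared = [(a, b) for a, b in zip(si, sj) if a != "-" and b != "-"]
            matches = sum(1 for a, b in shared if a == b)
            truth[(records[i][0], records[j][0])] = (matches, len(shared))
    return records, truth
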