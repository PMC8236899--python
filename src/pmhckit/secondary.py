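"""Backbone hydrogen bonds, secondary structure, and β-sheet topology.

The hydrogen-bond model is the classic Kabsch–Sander electrostatic term

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond accepted below -0.5 kcal/mol.  Crystal structures carry no
hydrogens, so the amide H is reconstructed 1.01 Å from N along the
direction opposite the bisector of the C(i-1)-N-CA angle.

Secondary-structure states follow the DSSP pattern rules (n-turns from
i -> i+n bonds, minimal helices from two consecutive turns, bridges and
ladders from the parallel/antiparallel bond patterns).  When helix
patterns overlap, a π pattern of minimal length overrides α, matching the
behaviour of modern DSSP releases that report π-helices; otherwise the
priority is α > 3₁₀ > π.

On top of the ladders sit two rule-based detectors for features that are
conserved across peptide-binding domains of both MHC classes:

* the classic **β-bulge** — two consecutive residues on one strand opposite
  a single residue on the partner strand, flanked by regular ladder pairs
  (at canonical positions p33/p34 of strand S3 in MHC p-domains);
* the **S2-S3 cleft** — truncated main-chain pairing between strands S2 and
  S3, where the outermost accepted pair is p24-p36 instead of extending to
  p22-p38 (present in the pb domain of class I and the pa domain of
  class II complexes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .numbering import DomainAssignment, NumberingMap
from .structures import Residue, Structure

__all__ = [
    "HydrogenBond",
    "SSAssignment",
    "BetaLadder",
    "BetaBulge",
    "CleftStatus",
    "kabsch_sander_energy",
    "reconstruct_amide_h",
    "compute_backbone_hbonds",
    "assign_secondary_structure",
    "build_beta_topology",
    "BetaTopology",
    "detect_beta_bulges",
    "detect_s2s3_cleft",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_Q = 0.084 * 332.0
_CA_PREFILTER = 9.0  # Å; lossless for the KS energy at the -0.5 threshold
_MIN_SEQ_SEPARATION = 2

STATES = ("alpha", "310", "pi", "strand", "turn", "coil")


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[str, int, str | None]     # residue key providing N-H
    acceptor: tuple[str, int, str | None]  # residue key providing C=O
    energy: float                          # kcal/mol, negative

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("hydrogen bond donor and acceptor must differ")


def _coords_of(res, name: str):
    """Accept either a Residue or a plain dict of atom coordinates."""
    if isinstance(res, dict):
        return res.get(name)
    return res.coord(name)


def kabsch_sander_energy(donor, acceptor, donor_h: np.ndarray | None = None) -> float:
    """Electrostatic H-bond energy between one N-H donor and one C=O acceptor.

    ``donor`` supplies N (and H via ``donor_h``); ``acceptor`` supplies C, O.
    Distances in Å, energy in kcal/mol; large separations give ~0.
    """
    n = _coords_of(donor, "N")
    c = _coords_of(acceptor, "C")
    o = _coords_of(acceptor, "O")
    if n is None or c is None or o is None or donor_h is None:
        return 0.0
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - donor_h)
    r_oh = np.linalg.norm(o - donor_h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # overlapping atoms: treat as clash
        return 0.0
    return _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def reconstruct_amide_h(residues) -> list[np.ndarray | None]:
    """Amide H per residue: 1.01 Å from N, opposite the C(i-1)-N-CA bisector.

    ``residues`` is a chain-ordered list of Residue objects or coordinate
    dicts.  The first residue of a chain (or any residue not peptide-bonded
    to its predecessor) has no reconstructed H.  Prolines have no amide H.
    """
    out: list[np.ndarray | None] = []
    for i, res in enumerate(residues):
        resname = res.resname if isinstance(res, Residue) else None
        n = _coords_of(res, "N")
        ca = _coords_of(res, "CA")
        if i == 0 or n is None or ca is None or resname == "PRO":
            out.append(None)
            continue
        c_prev = _coords_of(residues[i - 1], "C")
        if c_prev is None or np.linalg.norm(c_prev - n) > 2.5:
            out.append(None)
            continue
        v1 = c_prev - n
        v2 = ca - n
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        bisector = v1 + v2
        norm = np.linalg.norm(bisector)
        if norm < 1e-9:
            out.append(None)
            continue
        out.append(n - 1.01 * bisector / norm)
    return out


class _Backbone:
    """Chain-ordered residue index with reconstructed amide hydrogens."""

    def __init__(self, structure: Structure):
        self.residues: list[Residue] = []
        self.chain_of: list[str] = []
        self.h: list[np.ndarray | None] = []
        self.skipped: list[Residue] = []
        for chain_id, chain in structure.chains.items():
            usable = []
            for res in chain:
                if not res.is_standard_aa:
                    continue
                if res.coord("N") is None or res.coord("CA") is None or res.coord("C") is None:
                    self.skipped.append(res)
                    continue
                usable.append(res)
            hs = reconstruct_amide_h(usable)
            self.residues.extend(usable)
            self.chain_of.extend([chain_id] * len(usable))
            self.h.extend(hs)
        if self.skipped:
            warnings.warn(
                f"{len(self.skipped)} residue(s) skipped for missing backbone atoms",
                stacklevel=3,
            )
        self.key_to_idx = {r.key: i for i, r in enumerate(self.residues)}

    def bonded_through_chain(self, i: int, j: int) -> bool:
        """True when i..j are consecutive, peptide-bonded residues of one chain."""
        if self.chain_of[i] != self.chain_of[j]:
            return False
        lo, hi = min(i, j), max(i, j)
        for k in range(lo, hi):
            c = self.residues[k].coord("C")
            n = self.residues[k + 1].coord("N")
            if c is None or n is None or np.linalg.norm(c - n) > 2.5:
                return False
        return True

    def separation(self, i: int, j: int) -> int | None:
        """Sequence separation within a chain; None across chains/breaks."""
        if self.chain_of[i] != self.chain_of[j]:
            return None
        return abs(i - j)


def compute_backbone_hbonds(structure: Structure, use_prefilter: bool = True) -> list[HydrogenBond]:
    """All backbone N-H···O=C bonds below the Kabsch–Sander threshold.

    Donors and acceptors at sequence separation < 2 within a chain are
    excluded.  A 9 Å CA-CA prefilter bounds the pair scan; it is lossless
    at the -0.5 kcal/mol threshold (and can be disabled for oracle tests).
    """
    bb = _Backbone(structure)
    n = len(bb.residues)
    if n == 0:
        return []
    cas = np.array([r.coord("CA") for r in bb.residues])
    if use_prefilter:
        tree = cKDTree(cas)
        candidate_pairs = tree.query_pairs(_CA_PREFILTER)
        pairs = set()
        for i, j in candidate_pairs:
            pairs.add((i, j))
            pairs.add((j, i))
    else:
        pairs = {(i, j) for i in range(n) for j in range(n) if i != j}

    bonds: list[HydrogenBond] = []
    for donor_idx, acc_idx in sorted(pairs):
        if bb.h[donor_idx] is None:
            continue
        sep = bb.separation(donor_idx, acc_idx)
        if sep is not None and sep < _MIN_SEQ_SEPARATION:
            continue
        e = kabsch_sander_energy(
            bb.residues[donor_idx], bb.residues[acc_idx], donor_h=bb.h[donor_idx]
        )
        if e <= HBOND_ENERGY_CUTOFF:
            bonds.append(
                HydrogenBond(
                    donor=bb.residues[donor_idx].key,
                    acceptor=bb.residues[acc_idx].key,
                    energy=float(e),
                )
            )
    return bonds


@dataclass
class SSAssignment:
    """Per-residue secondary-structure state."""

    states: dict[tuple[str, int, str | None], str]
    order: list[tuple[str, int, str | None]]

    def state(self, key) -> str:
        return self.states.get(key, "coil")

    def as_rows(self):
        return [(key, self.states[key]) for key in self.order]


def assign_secondary_structure(hbonds: list[HydrogenBond],
                               structure: Structure) -> SSAssignment:
    """DSSP-style state assignment from the accepted hydrogen bonds."""
    bb = _Backbone(structure)
    n = len(bb.residues)
    idx = bb.key_to_idx
    # hb[(i, j)]: CO(i) accepts from NH(j)
    hb = set()
    for bond in hbonds:
        if bond.donor in idx and bond.acceptor in idx:
            hb.add((idx[bond.acceptor], idx[bond.donor]))

    def turn(i: int, k: int) -> bool:
        j = i + k
        return j < n and bb.bonded_through_chain(i, j) and (i, j) in hb

    states = ["coil"] * n

    # minimal helices: two consecutive n-turns start a helix at i..i+k-1
    helix_members: dict[str, set[int]] = {"alpha": set(), "310": set(), "pi": set()}
    for k, name in ((4, "alpha"), (3, "310"), (5, "pi")):
        for i in range(1, n):
            if turn(i - 1, k) and turn(i, k):
                helix_members[name].update(range(i, i + k))

    # bridges
    par, anti = set(), set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (_hb(hb, i - 1, j) and _hb(hb, j, i + 1)) or (
                _hb(hb, j - 1, i) and _hb(hb, i, j + 1)
            ):
                par.add((i, j))
            if (_hb(hb, i, j) and _hb(hb, j, i)) or (
                _hb(hb, i - 1, j + 1) and _hb(hb, j - 1, i + 1)
            ):
                anti.add((i, j))

    strand_members: set[int] = set()
    for ladder in _ladders_from_bridges(par, "parallel") + _ladders_from_bridges(
        anti, "antiparallel"
    ):
        if len(ladder) >= 2:  # singleton bridges stay bridges, not strands
            for i, j in ladder:
                strand_members.add(i)
                strand_members.add(j)

    # precedence: strand, then helices with pi-over-alpha when a full pi
    # pattern overlaps, then turns
    for i in range(n):
        if i in strand_members:
            states[i] = "strand"
    for i in range(n):
        if states[i] != "coil":
            continue
        if i in helix_members["pi"]:
            states[i] = "pi"
        elif i in helix_members["alpha"]:
            states[i] = "alpha"
        elif i in helix_members["310"]:
            states[i] = "310"
    # alpha keeps priority where pi overlap is not a complete pattern of its own
    for i in range(n):
        if states[i] == "pi" and i in helix_members["alpha"] and not _in_full_pi_run(
            i, helix_members["pi"]
        ):
            states[i] = "alpha"
    for i in range(n):
        if states[i] != "coil":
            continue
        if any(turn(i - k + m, k) for k in (3, 4, 5) for m in range(1, k)
               if 0 <= i - k + m):
            states[i] = "turn"
        elif _is_bend(bb, i):
            states[i] = "turn"

    keys = [r.key for r in bb.residues]
    return SSAssignment(states=dict(zip(keys, states)), order=keys)


def _hb(hb: set, i: int, j: int) -> bool:
    return (i, j) in hb


def _in_full_pi_run(i: int, pi_members: set[int]) -> bool:
    run = {i}
    k = i - 1
    while k in pi_members:
        run.add(k)
        k -= 1
    k = i + 1
    while k in pi_members:
        run.add(k)
        k += 1
    return len(run) >= 5


def _is_bend(bb: _Backbone, i: int) -> bool:
    if i < 2 or i + 2 >= len(bb.residues):
        return False
    if not bb.bonded_through_chain(i - 2, i + 2):
        return False
    a = bb.residues[i - 2].coord("CA")
    b = bb.residues[i].coord("CA")
    c = bb.residues[i + 2].coord("CA")
    u, v = b - a, c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.rad2deg(np.arccos(np.clip(cosang, -1, 1))) > 70.0


def _ladders_from_bridges(bridges: set[tuple[int, int]], sense: str):
    """Group bridges into ladders of consecutive rungs."""
    ladders: list[list[tuple[int, int]]] = []
    remaining = set(bridges)
    step = 1 if sense == "parallel" else -1
    for start in sorted(remaining):
        if start not in remaining:
            continue
        ladder = [start]
        remaining.discard(start)
        i, j = start
        while (i + 1, j + step) in remaining:
            i, j = i + 1, j + step
            ladder.append((i, j))
            remaining.discard((i, j))
        ladders.append(ladder)
    return ladders


@dataclass
class BetaLadder:
    strand_a: list[tuple[str, int, str | None]]
    strand_b: list[tuple[str, int, str | None]]
    sense: str
    paired_positions: list[tuple[tuple[str, int, str | None], tuple[str, int, str | None]]]


@dataclass
class BetaBulge:
    bulge_pair: tuple[tuple[str, int, str | None], tuple[str, int, str | None]]
    opposite_residue: tuple[str, int, str | None]
    sidechain_direction: str  # up | down | undetermined


@dataclass
class CleftStatus:
    domain_class: str
    last_pair: tuple[int, int] | None  # canonical (S2 position, S3 position)
    cleft_present: bool | None         # None = undetermined


_IGSF_ALIASES = dict(zip(range(1, 8), "ABCDEFG"))


@dataclass
class BetaTopology:
    ladders: list[BetaLadder]
    #: strand label per residue key, e.g. "pa:S2" or "ib:S5/E"; chains
    #: without a domain assignment are labelled "chain:S1" etc.
    strand_labels: dict[tuple[str, int, str | None], str]
    #: ordered residue runs per strand label
    strands: dict[str, list[tuple[str, int, str | None]]]
    bridges: list[tuple[tuple, tuple, str]] = field(default_factory=list)


def build_beta_topology(hbonds: list[HydrogenBond], structure: Structure,
                        assignment: SSAssignment | None = None,
                        domains: DomainAssignment | None = None,
                        nmap: NumberingMap | None = None) -> BetaTopology:
    """Ladders plus per-domain strand labels (S1… in sequence order).

    IgSF (ia/ib) strands additionally carry the conventional A-G aliases.
    Expected strand counts are 4 per p-domain and 7 per IgSF domain; other
    counts are labelled best-effort with a warning.
    """
    if assignment is None:
        assignment = assign_secondary_structure(hbonds, structure)
    bb = _Backbone(structure)
    idx = bb.key_to_idx
    hb = set()
    for bond in hbonds:
        if bond.donor in idx and bond.acceptor in idx:
            hb.add((idx[bond.acceptor], idx[bond.donor]))
    n = len(bb.residues)
    par, anti = set(), set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (_hb(hb, i - 1, j) and _hb(hb, j, i + 1)) or (
                _hb(hb, j - 1, i) and _hb(hb, i, j + 1)
            ):
                par.add((i, j))
            if (_hb(hb, i, j) and _hb(hb, j, i)) or (
                _hb(hb, i - 1, j + 1) and _hb(hb, j - 1, i + 1)
            ):
                anti.add((i, j))

    ladders = []
    bridge_list = []
    for sense, bridges in (("parallel", par), ("antiparallel", anti)):
        for rungs in _ladders_from_bridges(bridges, sense):
            for i, j in rungs:
                bridge_list.append((bb.residues[i].key, bb.residues[j].key, sense))
            if len(rungs) < 2:
                continue
            ladders.append(
                BetaLadder(
                    strand_a=[bb.residues[i].key for i, _ in rungs],
                    strand_b=[bb.residues[j].key for _, j in rungs],
                    sense=sense,
                    paired_positions=[
                        (bb.residues[i].key, bb.residues[j].key) for i, j in rungs
                    ],
                )
            )

    strand_labels, strands = _label_strands(bb, assignment, domains, nmap)
    return BetaTopology(ladders=ladders, strand_labels=strand_labels,
                        strands=strands, bridges=bridge_list)


_EXPECTED_STRANDS = {"pa": 4, "pb": 4, "ia": 7, "ib": 7}


def _label_strands(bb: _Backbone, assignment: SSAssignment,
                   domains: DomainAssignment | None,
                   nmap: NumberingMap | None):
    def group_of(res: Residue) -> str:
        if nmap is not None:
            cid = nmap.canonical(res.key)
            if cid is not None:
                return cid.domain_class
            return f"chain {res.author_chain}"
        return res.author_chain

    # strand segments: maximal chain-consecutive runs of residues in strand state
    segments: dict[str, list[list]] = {}
    current_group, current_run = None, []
    prev_idx = None
    for i, res in enumerate(bb.residues):
        in_strand = assignment.state(res.key) == "strand"
        grp = group_of(res) if in_strand else None
        contiguous = (
            prev_idx is not None and in_strand and grp == current_group
            and bb.bonded_through_chain(prev_idx, i)
        )
        if contiguous:
            current_run.append(res.key)
        else:
            if current_run:
                segments.setdefault(current_group, []).append(current_run)
            current_run = [res.key] if in_strand else []
            current_group = grp
        prev_idx = i if in_strand else None
    if current_run:
        segments.setdefault(current_group, []).append(current_run)

    labels: dict = {}
    strands: dict[str, list] = {}
    for group, runs in segments.items():
        expected = _EXPECTED_STRANDS.get(group)
        if expected is not None and len(runs) != expected:
            warnings.warn(
                f"{group}: found {len(runs)} strands, expected {expected}; "
                "labelling best-effort in sequence order",
                stacklevel=3,
            )
        for k, run in enumerate(runs, start=1):
            label = f"{group}:S{k}"
            if group in ("ia", "ib") and k in _IGSF_ALIASES:
                label += f"/{_IGSF_ALIASES[k]}"
            strands[label] = run
            for key in run:
                labels[key] = label
    return labels, strands


def detect_beta_bulges(topology: BetaTopology, structure: Structure,
                       domains: DomainAssignment | None = None) -> list[BetaBulge]:
    """Classic β-bulges from the antiparallel bridge pattern.

    A bulge is flagged where consecutive accepted rungs advance two
    positions on one strand but only one on the partner: the two consecutive
    residues between the flanking rungs form ``bulge_pair`` and the single
    partner residue is ``opposite_residue``.  The sidechain direction of the
    pair is reported relative to the local sheet plane ("up" = toward the
    mean helix centroid of the same structure when one exists, else the
    positive normal side).
    """
    bb = _Backbone(structure)
    idx = bb.key_to_idx
    anti = [
        (idx[a], idx[b]) for a, b, sense in topology.bridges
        if sense == "antiparallel" and a in idx and b in idx
    ]
    rungs = set(anti) | {(j, i) for i, j in anti}
    bulges: list[BetaBulge] = []
    seen = set()
    for i1, j1 in sorted(rungs):
        # Between consecutive accepted rungs (i1, j1) -> (i2, j2) of an
        # antiparallel ladder pair, the bulged strand skips exactly one
        # residue more than its partner.  With skip_a skipped partner
        # residues and skip_b = skip_a + 1 skipped bulge-strand residues,
        # the bulge pair is the first two skipped-strand residues after j2
        # and the opposite residue is the single partner residue between
        # the flanking rungs.
        for skip_a in (0, 1):
            i2 = i1 + skip_a + 1
            j2 = j1 - (skip_a + 2)
            if (i2, j2) not in rungs:
                continue
            # flanking rungs must belong to continuous strand runs
            if not bb.bonded_through_chain(i1, i2) or not bb.bonded_through_chain(j2, j1):
                continue
            # the skipped region must be genuinely unpaired
            blocked = False
            for ii in range(i1, i2 + 1):
                for jj in range(j2 + 1, j1):
                    if (ii, jj) in rungs:
                        blocked = True
            if blocked:
                continue
            b1, b2 = j1 - (skip_a + 1), j1 - skip_a
            pair = (bb.residues[b1].key, bb.residues[b2].key)
            if pair in seen:
                continue
            seen.add(pair)
            opposite = i1 + skip_a
            direction = _sidechain_direction(bb, b1, b2, opposite, structure)
            bulges.append(
                BetaBulge(
                    bulge_pair=pair,
                    opposite_residue=bb.residues[opposite].key,
                    sidechain_direction=direction,
                )
            )
    return bulges


def _sidechain_direction(bb: _Backbone, b1: int, b2: int, opp: int,
                         structure: Structure) -> str:
    cb1 = bb.residues[b1].coord("CB")
    cb2 = bb.residues[b2].coord("CB")
    ca1 = bb.residues[b1].coord("CA")
    ca2 = bb.residues[b2].coord("CA")
    if cb1 is None or cb2 is None:
        return "undetermined"
    # local sheet plane from the rung neighbourhood CA atoms
    pts = [bb.residues[k].coord("CA") for k in (b1 - 1, b1, b2, b2 + 1, opp)
           if 0 <= k < len(bb.residues) and bb.residues[k].coord("CA") is not None]
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    normal = _orient_normal(normal, centroid, structure, bb, (b1, b2))
    s = ((cb1 - ca1) @ normal) + ((cb2 - ca2) @ normal)
    return "up" if s > 0 else "down"


def _orient_normal(normal: np.ndarray, centroid: np.ndarray,
                   structure: Structure, bb: _Backbone,
                   exclude: tuple[int, ...]) -> np.ndarray:
    """Point the sheet normal toward "up" in the groove frame.

    "Up" is the side holding the mean CA centroid of the structure's
    helices.  For pure-sheet inputs with no helix, the fallback is the
    majority sidechain side of the remaining strand residues (excluding
    the bulge pair itself), which is rigid-transform invariant.
    """
    try:
        hbonds = compute_backbone_hbonds(structure)
        ss = assign_secondary_structure(hbonds, structure)
        helix_cas = [
            r.coord("CA") for r in structure.residues()
            if ss.state(r.key) in ("alpha", "310", "pi") and r.coord("CA") is not None
        ]
    except Exception:  # pragma: no cover - defensive
        helix_cas = []
    if helix_cas:
        toward = np.mean(helix_cas, axis=0) - centroid
        if normal @ toward < 0:
            return -normal
        return normal
    excluded = set(exclude)
    majority = np.zeros(3)
    for k, res in enumerate(bb.residues):
        if k in excluded:
            continue
        ca, cb = res.coord("CA"), res.coord("CB")
        if ca is not None and cb is not None:
            majority += cb - ca
    if abs(majority @ normal) > 1e-6 and majority @ normal < 0:
        return -normal
    return normal


def detect_s2s3_cleft(topology: BetaTopology, domain_class: str,
                      nmap: NumberingMap) -> CleftStatus:
    """Is the S2-S3 main-chain pairing of this p-domain truncated at p24-p36?

    Decided only from accepted main-chain hydrogen-bond rungs (never CA
    distances): the outermost rung between strands S2 and S3 is located in
    canonical numbering; the cleft is present exactly when that rung is the
    p24-p36 pair, absent when pairing extends outward (e.g. to p22-p38),
    and undetermined when S2/S3 cannot be identified.
    """
    if domain_class not in ("pa", "pb"):
        raise ValueError("S2-S3 cleft is defined for p-domains only")
    s2 = topology.strands.get(f"{domain_class}:S2")
    s3 = topology.strands.get(f"{domain_class}:S3")
    if not s2 or not s3:
        return CleftStatus(domain_class=domain_class, last_pair=None, cleft_present=None)
    s2_set, s3_set = set(s2), set(s3)
    rung_positions = []
    for a, b, sense in topology.bridges:
        if sense != "antiparallel":
            continue
        pair = None
        if a in s2_set and b in s3_set:
            pair = (a, b)
        elif b in s2_set and a in s3_set:
            pair = (b, a)
        if pair is None:
            continue
        cid2, cid3 = nmap.canonical(pair[0]), nmap.canonical(pair[1])
        if cid2 is None or cid3 is None:
            continue
        rung_positions.append((cid2.position, cid3.position))
    if not rung_positions:
        return CleftStatus(domain_class=domain_class, last_pair=None, cleft_present=None)
    # outermost: smallest S2 position (ties: largest S3 position)
    last_pair = min(rung_positions, key=lambda p: (p[0], -p[1]))
    return CleftStatus(
        domain_class=domain_class,
        last_pair=last_pair,
        cleft_present=(last_pair == (24, 36)),
    )
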