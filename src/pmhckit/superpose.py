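"""Rigid-body least-squares superposition of domains between structures.

Correspondences come from the canonical numbering maps rather than from a
sequence-independent structural aligner: two residues correspond exactly
when they carry the same canonical (domain, position) label.  The fit is
the standard Kabsch algorithm (SVD of the cross-covariance, reflection
excluded), CA-only by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .numbering import CanonicalResidueID, NumberingMap
from .structures import Structure

__all__ = ["RigidTransform", "SuperpositionResult", "kabsch_fit", "superpose_by_domain"]


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray     # 3x3, orthonormal, det = +1
    translation: np.ndarray  # 3-vector, Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid transforms")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_fitted: int
    correspondence: list[tuple[CanonicalResidueID, CanonicalResidueID]]
    transformed: Structure | None = None


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD.  Requires >= 3 points and
    non-degenerate (non-collinear) geometry; reflections are excluded by
    sign correction of the smallest singular vector.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if _collinear(P0) or _collinear(Q0):
        raise ValueError("degenerate input: points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _collinear(centred: np.ndarray, tol: float = 1e-8) -> bool:
    s = np.linalg.svd(centred, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def superpose_by_domain(
    mobile: Structure,
    mobile_map: NumberingMap,
    reference: Structure,
    reference_map: NumberingMap,
    selector: str | list[str] = "pab",
    atoms: tuple[str, ...] = ("CA",),
) -> SuperpositionResult:
    """Fit the mobile structure onto the reference over shared canonical
    positions of the selected domain(s) and return the transformed copy.

    ``selector`` is a domain class, ``"pab"``, or a list of classes.
    Residues missing any requested atom are dropped from the correspondence.
    """
    wanted = _selector_classes(selector)
    mob_xyz, ref_xyz, pairs = [], [], []
    ref_lookup = {
        cid: key for key, cid in reference_map.forward.items()
        if cid.domain_class in wanted
    }
    n_dropped = 0
    for key, cid in sorted(mobile_map.forward.items(),
                           key=lambda kv: (kv[1].domain_class, kv[1].position,
                                           kv[1].icode or "", kv[1].register or 0)):
        if cid.domain_class not in wanted or cid not in ref_lookup:
            continue
        res_m = mobile.residue(*key)
        res_r = reference.residue(*ref_lookup[cid])
        if res_m is None or res_r is None:
            continue
        coords_m = [res_m.coord(a) for a in atoms]
        coords_r = [res_r.coord(a) for a in atoms]
        if any(c is None for c in coords_m + coords_r):
            n_dropped += 1
            continue
        mob_xyz.extend(coords_m)
        ref_xyz.extend(coords_r)
        pairs.append((cid, cid))
    if len(pairs) < 3:
        raise ValueError(
            f"selector {selector!r}: only {len(pairs)} shared canonical "
            "positions with complete atoms (need >= 3)"
        )
    transform, rmsd = kabsch_fit(np.array(mob_xyz), np.array(ref_xyz))
    moved = mobile.transformed(transform.rotation, transform.translation)
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        n_fitted=len(pairs),
        correspondence=pairs,
        transformed=moved,
    )


def _selector_classes(selector: str | list[str]) -> set[str]:
    if isinstance(selector, str):
        if selector == "pab":
            return {"pa", "pb"}
        return {selector}
    out: set[str] = set()
    for s in selector:
        out |= _selector_classes(s)
    return out
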