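"""Core vector geometry: centroids, ring planes, torsions, superposition.

All angles are in degrees and all lengths in Angstrom.  Torsions follow the
IUPAC sign convention and are reported in (-180, 180].  Superposition is the
least-squares optimal proper rotation (Kabsch), computed through
``scipy.spatial.transform.Rotation.align_vectors`` after centering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from mhcgroove.errors import GeometryError
from mhcgroove.structure_io import Structure, select_atom

__all__ = [
    "centroid",
    "ring_normal",
    "angle_between",
    "dihedral",
    "dihedral_series",
    "kabsch",
    "superpose",
    "atom_shift",
    "SuperpositionResult",
    "shared_calpha_selection",
]

AtomAddress = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


def centroid(points: Sequence) -> np.ndarray:
    """Arithmetic mean of a set of coordinate triples (the 'geometrical
    center' used for aromatic rings)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise GeometryError("centroid of an empty point set is undefined")
    pts = pts.reshape(-1, 3)
    return pts.mean(axis=0)


def ring_normal(points: Sequence) -> np.ndarray:
    """Unit normal of the best-fit plane through >= 3 points.

    The normal is the smallest-variance principal axis of the centered
    coordinates, which minimises the squared out-of-plane deviation and is
    robust to slight non-planarity.  Sign convention: the first component
    of the vector that is not (numerically) zero is made nonnegative, so
    the result is deterministic.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise GeometryError("ring_normal needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    # SVD of the centered coordinates: right-singular vector of the smallest
    # singular value spans the out-of-plane direction.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-8:  # only one independent in-plane direction
        raise GeometryError("points are collinear; plane normal undefined")
    n = vt[2]
    for comp in n:
        if abs(comp) > 1e-12:
            if comp < 0:
                n = -n
            break
    return n / np.linalg.norm(n)


def angle_between(v1, v2, fold: str = "none") -> float:
    """Angle between two vectors in degrees.

    ``fold="none"`` / ``"fold_180"`` report the arccos angle in [0, 180];
    ``"fold_90"`` maps theta > 90 to 180 - theta, the line-line angle in
    [0, 90].  Ring-orientation analysis uses the [0, 180] range, on which
    e.g. a near-parallel ring pair can appear at either ~0 or ~150-180
    depending on the normals' signs.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("angle_between requires nonzero vectors")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cosang)))
    if fold == "fold_90" and theta > 90.0:
        theta = 180.0 - theta
    elif fold not in ("none", "fold_180", "fold_90"):
        raise GeometryError(f"unknown fold mode {fold!r}")
    return theta


def _dihedral_arrays(a, b, c, d) -> np.ndarray:
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # IUPAC sign: positive when d rotates clockwise viewed down b->c
    ang = np.degrees(np.arctan2(-y, x))
    # principal range (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral(a, b, c, d) -> float:
    """Signed IUPAC torsion of the chain a-b-c-d, degrees in (-180, 180].

    Viewed down the b->c axis, the angle from the a-b-c plane to the
    b-c-d plane is positive clockwise.
    """
    pts = [np.asarray(p, dtype=float) for p in (a, b, c, d)]
    for p, q in zip(pts[:-1], pts[1:]):
        if np.linalg.norm(q - p) < 1e-9:
            raise GeometryError("coincident consecutive points; torsion undefined")
    return float(_dihedral_arrays(*pts))


def dihedral_series(a, b, c, d) -> np.ndarray:
    """Vectorised :func:`dihedral` over stacked (n, 3) coordinate arrays."""
    arrs = [np.asarray(p, dtype=float) for p in (a, b, c, d)]
    for p, q in zip(arrs[:-1], arrs[1:]):
        if np.any(np.linalg.norm(q - p, axis=-1) < 1e-9):
            raise GeometryError("coincident consecutive points in some frame")
    return _dihedral_arrays(*arrs)


@dataclass
class SuperpositionResult:
    """Rigid-body fit of a mobile onto a reference structure."""

    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # applied after rotation
    rmsd: float               # over the fitted selection, Angstrom
    atom_count: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform (..., 3) mobile-frame coordinates into the reference frame."""
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps({
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "atom_count": self.atom_count,
        }, indent=2)


def kabsch(mobile_coords: np.ndarray, reference_coords: np.ndarray
           ) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation on paired points."""
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(reference_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("paired coordinate arrays of shape (n, 3) required")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("superposition needs >= 3 paired atoms")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    Pc, Qc = P - p_mean, Q - q_mean
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise GeometryError("selection is collinear; rotation underdetermined")
    rot, rssd = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = q_mean - R @ p_mean
    rmsd = float(rssd / np.sqrt(n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, atom_count=n)


def _gather(s: Structure, selection: Sequence[AtomAddress]) -> np.ndarray:
    return np.array([select_atom(s, *addr).position for addr in selection])


def superpose(mobile: Structure, reference: Structure,
              selection: Sequence[AtomAddress]) -> SuperpositionResult:
    """Kabsch-fit ``mobile`` onto ``reference`` over a shared atom selection.

    ``selection`` is a list of ``(chain_id, residue_number, atom_name)``
    addresses that must resolve in both structures.
    """
    P = _gather(mobile, selection)
    Q = _gather(reference, selection)
    return kabsch(P, Q)


def atom_shift(mobile: Structure, reference: Structure,
               superposition_selection: Sequence[AtomAddress],
               probe: AtomAddress) -> float:
    """Displacement (Angstrom) of one probe atom between two structures
    after superposing on a selection.

    This is the statistic behind 'Calpha shift at P1' comparisons: the
    Euclidean distance between the reference probe atom and the transformed
    mobile probe atom.
    """
    sup = superpose(mobile, reference, superposition_selection)
    pm = select_atom(mobile, *probe).position
    pr = select_atom(reference, *probe).position
    return float(np.linalg.norm(sup.apply(pm) - pr))


def shared_calpha_selection(a: Structure, b: Structure, chain_id: str,
                            residue_range: tuple[int, int] = (1, 180),
                            ) -> list[AtomAddress]:
    """CA atoms of one chain resolved in BOTH structures within a range.

    This is the package's superposition frame for inter-structure groove
    comparisons: restricting to mutually resolved Calpha keeps comparisons
    well-defined when one structure has disordered (missing) stretches.
    """
    first, last = residue_range
    sel: list[AtomAddress] = []
    for num in range(first, last + 1):
        ok = True
        for s in (a, b):
            ch = s.chain(chain_id)
            res = ch.residue(num) if ch is not None else None
            if res is None or res.is_water or res.atom("CA") is None:
                ok = False
                break
        if ok:
            sel.append((chain_id, num, "CA"))
    return sel
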