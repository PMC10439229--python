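"""Ground-truth fixture generator for groove/peptide analyses.

The scaffold is a geometric idealisation of an MHC class I heavy chain with
a bound peptide, not a physical conformer: residues sit on a regular
helical path with chemically plausible bond lengths (1.2-1.6 Angstrom) and
planar aromatic rings, and the peptide's position-1 side chain is planted
at prescribed distances/angles from Ile52 and Tyr59 so that every analysis
operation can be checked against a ledger of known values.  Trajectories
realise prescribed omega rotation schedules and descriptor distance
schedules exactly before seeded isotropic Gaussian noise is added.

Every generator returns ``(object, ledger)`` where the ledger is a plain
JSON-serialisable dict of the planted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from mhcgroove.errors import ValidationError
from mhcgroove.geometry import dihedral
from mhcgroove.structure_io import Atom, Chain, PeptideMap, Residue, Structure

__all__ = [
    "ScaffoldSpec",
    "TrajectorySpec",
    "make_scaffold",
    "make_trajectory",
    "sample_descriptor_population",
    "DEFAULT_SPECIAL_RESIDUES",
    "DEFAULT_PEPTIDE_POSITIONS",
]

# Conserved groove residues by author number (pocket A/B neighbourhood plus
# the 3-10 helix support Ile52 and the disulfide anchor Cys76).
DEFAULT_SPECIAL_RESIDUES: dict[int, str] = {
    7: "TYR", 52: "ILE", 59: "TYR", 62: "ARG", 63: "ASN",
    76: "CYS", 159: "TYR", 167: "TRP", 171: "TYR",
}

# Core positions P1-P8 of a Phe1/Ala2 peptide with N-terminal extension
# residues P-1 (Ala) and P-2 (Arg) protruding from the groove.
DEFAULT_PEPTIDE_POSITIONS: dict[str, str] = {
    "P-2": "ARG", "P-1": "ALA", "P1": "PHE", "P2": "ALA", "P3": "LYS",
    "P4": "LYS", "P5": "LYS", "P6": "TYR", "P7": "CYS", "P8": "LEU",
}

_RING_SIDE = 1.39   # regular-hexagon side == circumradius, Angstrom
_CH_BOND = 1.09
_TETRAHEDRAL = 109.47


@dataclass
class ScaffoldSpec:
    """Recipe for one idealised groove + peptide structure."""

    heavy_chain_length: int = 180
    special_residues: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIAL_RESIDUES))
    peptide_positions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PEPTIDE_POSITIONS))
    gap_ranges: list[tuple[int, int]] = field(default_factory=list)
    geometry_seed: int = 0
    heavy_chain_id: str = "A"
    peptide_chain_id: str = "C"
    # planted pocket geometry
    p1_ile52_distance: float = 5.0       # ring centroid (or Cbeta) to Ile52 CD1
    p1_ile52_ch_angle: float = 135.0     # C-H-X angle at the anti methyl H
    p1_tyr59_distance: float = 6.0       # ring centroid (or Cbeta) to Tyr59 ring center
    p1_tyr59_ring_angle: float = 90.0    # angle between the two ring normals
    omega_deg: float | None = None       # planted omega; None keeps as built
    pocket_waters: int = 0               # waters chained off Tyr59 OH at 2.8 A

    def validate(self) -> None:
        if self.heavy_chain_length < 1:
            raise ValidationError("heavy_chain_length must be >= 1")
        for num in self.special_residues:
            if not 1 <= num <= self.heavy_chain_length:
                raise ValidationError(
                    f"special residue {num} outside chain 1..{self.heavy_chain_length}")
        for start, end in self.gap_ranges:
            if start > end or start < 1 or end > self.heavy_chain_length:
                raise ValidationError(f"gap range [{start}, {end}] invalid")
        for a, b in zip(sorted(self.gap_ranges), sorted(self.gap_ranges)[1:]):
            if b[0] <= a[1]:
                raise ValidationError("gap ranges overlap")
        if self.p1_ile52_distance <= _CH_BOND or self.p1_tyr59_distance <= 0:
            raise ValidationError("planted distances must be positive (> C-H bond)")
        if not 90.0 < self.p1_ile52_ch_angle < 180.0:
            raise ValidationError("CH-pi planted angle must lie in (90, 180)")
        if not 0.0 <= self.p1_tyr59_ring_angle <= 180.0:
            raise ValidationError("ring-orientation angle must lie in [0, 180]")


@dataclass
class TrajectorySpec:
    """Recipe for a synthetic conformational ensemble over a scaffold."""

    n_frames: int = 100
    frame_interval: float = 20.0  # ps between saved frames
    # {"kind": "constant"|"linear_ramp"|"piecewise", ...} or an explicit array
    omega_schedule: Mapping | Sequence[float] | None = None
    # descriptor name -> schedule; supported: "P1..Y59", "P1..I52"
    descriptor_schedules: dict[str, Mapping | Sequence[float]] = field(
        default_factory=dict)
    # None, a global sigma, or {"default": s, 52: s52, ("C", 3): sp1, ...}
    positional_noise_sigma: float | Mapping | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0 ps")
        if len(self.descriptor_schedules) > 1:
            raise ValidationError(
                "only one descriptor schedule at a time (they move the same "
                "peptide side chain)")
        for name in self.descriptor_schedules:
            if name not in ("P1..Y59", "P1..I52"):
                raise ValidationError(f"unsupported descriptor schedule {name!r}")


# ---------------------------------------------------------------------------
# small vector helpers (kept local so the generator's forward geometry stays
# an independent path from the analysis modules it is used to test)
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError("degenerate direction in scaffold construction")
    return v / n


def _perp(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Component of v perpendicular to a unit axis."""
    return v - np.dot(v, axis) * axis


def _any_perp(axis: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(_perp(trial, axis))


def _rotate(points: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray,
            angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of points about a line."""
    k = _unit(axis_dir)
    th = math.radians(angle_deg)
    p = np.atleast_2d(points) - axis_point
    rot = (p * math.cos(th)
           + np.cross(np.broadcast_to(k, p.shape), p) * math.sin(th)
           + np.outer(p @ k, k) * (1 - math.cos(th)))
    out = rot + axis_point
    return out[0] if np.asarray(points).ndim == 1 else out


def _close_link(p_start: np.ndarray, p_end: np.ndarray, r1: float, r2: float,
                side: np.ndarray) -> np.ndarray:
    """Point at distance r1 from p_start and r2 from p_end, on the ``side``
    half of the two-sphere intersection circle."""
    d = np.linalg.norm(p_end - p_start)
    if d > r1 + r2 or d < abs(r1 - r2) or d < 1e-9:
        raise ValidationError(
            f"two-sphere closure infeasible: d={d:.3f}, r1={r1}, r2={r2}")
    g = _unit(p_end - p_start)
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = math.sqrt(max(r1 * r1 - a * a, 0.0))
    lateral = _perp(side, g)
    lat = _unit(lateral) if np.linalg.norm(lateral) > 1e-9 else _any_perp(g)
    return p_start + a * g + h * lat


def _aromatic_ring(attach: np.ndarray, direction: np.ndarray,
                   normal: np.ndarray, names: Sequence[str],
                   bond: float = 1.45) -> dict[str, np.ndarray]:
    """Planar regular hexagon bonded to ``attach``; the first named atom is
    the vertex bonded to ``attach``."""
    n = _unit(normal)
    d = _unit(_perp(direction, n))
    first = attach + bond * d
    center = first + _RING_SIDE * d
    e1 = _unit(first - center)
    e2 = np.cross(n, e1)
    out = {}
    for k, name in enumerate(names):
        phi = math.radians(60.0 * k)
        out[name] = center + _RING_SIDE * (math.cos(phi) * e1 + math.sin(phi) * e2)
    out["_center"] = center
    out["_normal"] = n
    return out


def _staggered_methyl_hs(cd: np.ndarray, parent: np.ndarray, ref: np.ndarray
                         ) -> list[np.ndarray]:
    """The three staggered methyl hydrogens on ``cd`` (azimuths 60/180/300
    degrees from ``ref``, a substituent of ``parent``); generator-side
    formula, kept independent of the analysis module."""
    axis = _unit(cd - parent)
    e1 = _unit(_perp(ref - parent, axis))
    e2 = np.cross(axis, e1)
    cos_t = math.cos(math.radians(180.0 - _TETRAHEDRAL))
    sin_t = math.sin(math.radians(180.0 - _TETRAHEDRAL))
    out = []
    for phi_deg in (60.0, 180.0, 300.0):
        phi = math.radians(phi_deg)
        direction = cos_t * axis + sin_t * (math.cos(phi) * e1
                                            + math.sin(phi) * e2)
        out.append(cd + _CH_BOND * direction)
    return out


def _anti_methyl_h(cd: np.ndarray, parent: np.ndarray, ref: np.ndarray
                   ) -> np.ndarray:
    """The staggered methyl hydrogen on ``cd`` anti to ``ref``."""
    return _staggered_methyl_hs(cd, parent, ref)[1]


def _sign_normalized(n: np.ndarray) -> np.ndarray:
    """Deterministic normal orientation: first non-zero component made
    nonnegative (the package-wide plane-normal convention)."""
    for comp in n:
        if abs(comp) > 1e-12:
            return -n if comp < 0 else n
    return n


def _normal_pair_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals on the [0, 180] reporting scale,
    after sign normalisation of each."""
    a, b = _sign_normalized(_unit(n1)), _sign_normalized(_unit(n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(a, b))))))


def _angle_at(p_vertex: np.ndarray, p_a: np.ndarray, p_b: np.ndarray) -> float:
    va, vb = p_a - p_vertex, p_b - p_vertex
    c = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# backbone builder
# ---------------------------------------------------------------------------

def _build_backbone(ca_path: np.ndarray) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O positions for a chain of residues along a CA path, with the
    peptide links closed so every bond is 1.23-1.53 Angstrom."""
    n_res = ca_path.shape[0]
    out: list[dict[str, np.ndarray]] = [{"CA": ca_path[i].copy()} for i in range(n_res)]
    laterals = []
    for i in range(n_res):
        prev_i, next_i = max(i - 1, 0), min(i + 1, n_res - 1)
        tangent = _unit(ca_path[next_i] - ca_path[prev_i])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, tangent)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        laterals.append(_unit(np.cross(tangent, ref)))
    for i in range(n_res):
        ca = ca_path[i]
        b = laterals[i]
        if i + 1 < n_res:
            nxt = ca_path[i + 1]
            d = np.linalg.norm(nxt - ca)
            # place C so that |C - CA(i+1)| sits mid-feasible for the N link
            target = min(max(d - 1.35, 0.6), 1.33 + 1.46 - 0.35)
            cos_phi = (d * d + 1.52 ** 2 - target * target) / (2 * d * 1.52)
            cos_phi = max(-1.0, min(1.0, cos_phi))
            sin_phi = math.sqrt(1 - cos_phi ** 2)
            g = _unit(nxt - ca)
            b_perp = _unit(_perp(b, g))
            c_pos = ca + 1.52 * (cos_phi * g + sin_phi * b_perp)
            out[i]["C"] = c_pos
            out[i + 1]["N"] = _close_link(c_pos, nxt, 1.33, 1.46, b)
        else:
            g = _unit(ca - ca_path[i - 1]) if n_res > 1 else np.array([1.0, 0.0, 0.0])
            out[i]["C"] = ca + 1.52 * _unit(g + 0.35 * b)
        if i == 0:
            g = _unit(ca_path[1] - ca) if n_res > 1 else np.array([1.0, 0.0, 0.0])
            out[0]["N"] = ca + 1.46 * _unit(-g + 0.35 * b)
        out[i]["O"] = out[i]["C"] + 1.23 * _unit(
            _unit(out[i]["C"] - ca) + 0.9 * b)
    return out


def _generic_cb(ca: np.ndarray, n: np.ndarray, c: np.ndarray) -> np.ndarray:
    away = _unit(2 * ca - n - c)
    side = _unit(np.cross(c - ca, n - ca))
    return ca + 1.53 * _unit(away + 0.6 * side)


# ---------------------------------------------------------------------------
# the scaffold
# ---------------------------------------------------------------------------

def make_scaffold(spec: ScaffoldSpec | None = None
                  ) -> tuple[Structure, dict]:
    """Build an idealised groove + peptide structure with a ground-truth
    ledger of every planted gap, descriptor value and contact.

    The heavy chain runs along a regular helical path; Ile52 and Tyr59 side
    chains reach toward a shared pocket point between them, and the peptide
    P1 side chain is planted so that the P1..Ile52 distance, the CH-pi
    angle at the anti methyl hydrogen, the P1..Tyr59 distance and the ring
    orientation angle match the spec.  Gaps are removed from the heavy
    chain only after planting, so a gapped scaffold mirrors a structure
    whose disordered residues were present in the template used to plant
    the peptide.
    """
    spec = spec or ScaffoldSpec()
    spec.validate()
    rng = np.random.default_rng([spec.geometry_seed, 101])

    L = spec.heavy_chain_length
    radius, rise, twist = 2.3, 1.5, 100.0
    numbers = np.arange(1, L + 1)
    theta = np.radians(twist * numbers)
    ca_path = np.column_stack([radius * np.cos(theta),
                               radius * np.sin(theta),
                               rise * numbers])
    backbone = _build_backbone(ca_path)
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(L)])

    names = {n: spec.special_residues.get(n, "ALA") for n in numbers}
    atoms_by_residue: dict[int, dict[str, np.ndarray]] = {
        int(n): dict(backbone[i]) for i, n in enumerate(numbers)}

    # pocket point between Ile52 and Tyr59 side chains (when both exist)
    has_pocket = names.get(52) == "ILE" and names.get(59) == "TYR"
    ring_centers: dict[int, np.ndarray] = {}
    ring_normals: dict[int, np.ndarray] = {}
    if has_pocket:
        ca52, ca59 = atoms_by_residue[52]["CA"], atoms_by_residue[59]["CA"]
        r_mean = _unit(radial[51] + radial[58])
        pocket = 0.5 * (ca52 + ca59) + 3.2 * r_mean

    for i, n in enumerate(numbers):
        n = int(n)
        res_name = names[n]
        res_atoms = atoms_by_residue[n]
        if res_name == "GLY":
            continue
        ca, nn, cc = res_atoms["CA"], res_atoms["N"], res_atoms["C"]
        out_dir = radial[i]
        if has_pocket and n in (52, 59):
            out_dir = _unit(pocket - ca)
        cb = ca + 1.53 * _unit(out_dir + 0.25 * np.array([0.0, 0.0, 1.0]))
        res_atoms["CB"] = cb
        tangent = _unit(ca_path[min(i + 1, L - 1)] - ca_path[max(i - 1, 0)])
        if res_name in ("TYR", "PHE"):
            ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
            ring = _aromatic_ring(cb, out_dir, tangent, ring_names, bond=1.50)
            for k in ring_names:
                res_atoms[k] = ring[k]
            ring_centers[n] = ring["_center"]
            ring_normals[n] = ring["_normal"]
            if res_name == "TYR":
                res_atoms["OH"] = ring["CZ"] + 1.36 * _unit(ring["CZ"] - ring["_center"])
        elif res_name == "TRP":
            res_atoms["CG"] = cb + 1.50 * _unit(out_dir)
            ring_names = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
            ring = _aromatic_ring(res_atoms["CG"], out_dir, tangent,
                                  ring_names, bond=1.43)
            for k in ring_names:
                res_atoms[k] = ring[k]
            ring_centers[n] = ring["_center"]
            ring_normals[n] = ring["_normal"]
        elif res_name == "ILE":
            bend = _unit(np.cross(out_dir, tangent))
            cg1 = cb + 1.53 * _unit(out_dir + 0.35 * bend)
            cd1 = cg1 + 1.53 * _unit(out_dir - 0.25 * bend)
            res_atoms["CG1"] = cg1
            res_atoms["CG2"] = cb + 1.53 * _unit(out_dir - 0.7 * bend + 0.4 * tangent)
            res_atoms["CD1"] = cd1
        elif res_name == "CYS":
            res_atoms["SG"] = cb + 1.55 * _unit(out_dir)
        elif res_name == "ASN":
            cg = cb + 1.52 * _unit(out_dir)
            res_atoms["CG"] = cg
            side = _unit(np.cross(out_dir, tangent))
            res_atoms["OD1"] = cg + 1.23 * _unit(out_dir + 0.9 * side)
            res_atoms["ND2"] = cg + 1.33 * _unit(out_dir - 0.9 * side)
        elif res_name == "ARG":
            d = _unit(out_dir)
            side = _unit(np.cross(out_dir, tangent))
            res_atoms["CG"] = cb + 1.52 * _unit(d + 0.3 * side)
            res_atoms["CD"] = res_atoms["CG"] + 1.52 * _unit(d - 0.2 * side)
            res_atoms["NE"] = res_atoms["CD"] + 1.46 * _unit(d + 0.2 * side)
            res_atoms["CZ"] = res_atoms["NE"] + 1.33 * d
            res_atoms["NH1"] = res_atoms["CZ"] + 1.33 * _unit(d + 0.8 * side)
            res_atoms["NH2"] = res_atoms["CZ"] + 1.33 * _unit(d - 0.8 * side)

    # ------------------------------------------------------------------
    # peptide planting
    # ------------------------------------------------------------------
    peptide_labels = sorted(
        spec.peptide_positions,
        key=lambda lab: (k := int(lab[1:]), k if k < 0 else k - 1))
    if "P1" not in spec.peptide_positions:
        raise ValidationError("peptide_positions must include P1")
    p1_index = peptide_labels.index("P1")
    p1_name = spec.peptide_positions["P1"]
    p1_aromatic = p1_name in ("PHE", "TYR", "TRP")

    ledger: dict = {
        "seed": spec.geometry_seed,
        "heavy_chain_id": spec.heavy_chain_id,
        "peptide_chain_id": spec.peptide_chain_id,
        "p1_number": p1_index + 1,
        "peptide_labels": peptide_labels,
        "gaps": [list(g) for g in sorted(spec.gap_ranges)],
        "descriptors": {},
        "contacts": [],
    }

    peptide_atoms: dict[str, dict[str, np.ndarray]] = {}
    if has_pocket:
        cd1 = atoms_by_residue[52]["CD1"]
        cg1 = atoms_by_residue[52]["CG1"]
        cb52 = atoms_by_residue[52]["CB"]
        y59_center = ring_centers[59]
        y59_normal = ring_normals[59]
        d1 = spec.p1_ile52_distance
        d2 = spec.p1_tyr59_distance
        if p1_aromatic:
            alpha = math.radians(spec.p1_ile52_ch_angle)
            h_anti = _anti_methyl_h(cd1, cg1, cb52)
            u_h = _unit(h_anti - cd1)

            def angle_mismatch(c: float) -> float:
                num = _CH_BOND - d1 * c
                den = math.sqrt(d1 * d1 + _CH_BOND ** 2 - 2 * _CH_BOND * d1 * c)
                return num / den - math.cos(alpha)

            c = brentq(angle_mismatch, -1.0, 1.0, xtol=1e-12)
            s = math.sqrt(max(0.0, 1 - c * c))
            m1 = _unit(_perp(y59_center - cd1, u_h))
            m2 = np.cross(u_h, m1)

            def x_of(psi: float) -> np.ndarray:
                return cd1 + d1 * (c * u_h + s * (math.cos(psi) * m1
                                                  + math.sin(psi) * m2))

            def dist_mismatch(psi: float) -> float:
                return float(np.linalg.norm(x_of(psi) - y59_center)) - d2

            grid = np.linspace(-math.pi, math.pi, 721)
            vals = np.array([dist_mismatch(p) for p in grid])
            exact = None
            for a_, b_ in zip(range(len(grid) - 1), range(1, len(grid))):
                if vals[a_] == 0.0 or vals[a_] * vals[b_] < 0:
                    exact = brentq(dist_mismatch, grid[a_], grid[b_], xtol=1e-12)
                    break
            psi = exact if exact is not None else float(grid[np.argmin(np.abs(vals))])
            x_center = x_of(psi)
            achieved_d2 = float(np.linalg.norm(x_center - y59_center))

            theta = math.radians(spec.p1_tyr59_ring_angle)
            m_dir = _perp(x_center - y59_center, y59_normal)
            m_dir = _unit(m_dir) if np.linalg.norm(m_dir) > 1e-9 else _any_perp(y59_normal)
            p1_normal = math.cos(theta) * y59_normal + math.sin(theta) * m_dir
            w = _unit(_perp(x_center - cd1, p1_normal))
            ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
            e1 = w
            e2 = np.cross(p1_normal, e1)
            p1_ring = {}
            for k, name in enumerate(ring_names):
                phi = math.radians(60.0 * k)
                p1_ring[name] = x_center + _RING_SIDE * (
                    math.cos(phi) * e1 + math.sin(phi) * e2)
            cg = p1_ring["CG"]
            cb_p1 = cg + 1.50 * _unit(w + 0.35 * p1_normal)
            ca_p1 = cb_p1 + 1.53 * _unit(w + 0.9 * p1_normal)
            p1_side = dict(p1_ring)
            p1_side["CB"] = cb_p1
            # ledger the angle at whichever staggered H points most linearly
            # toward the ring (the detection convention for a constructed H)
            achieved_alpha = max(
                _angle_at(h, cd1, x_center)
                for h in _staggered_methyl_hs(cd1, cg1, cb52))
            ledger["descriptors"].update({
                "P1..I52": d1,
                "P1..I52_ch_pi_angle": achieved_alpha,
                "P1..Y59": achieved_d2,
                # the planted inter-plane angle on the sign-normalised
                # [0, 180] reporting scale (theta and 180-theta describe the
                # same ring pairing; the convention picks one)
                "P1..Y59_ring_angle": _normal_pair_angle(p1_normal, y59_normal),
                "P1..Y59_ring_angle_folded": min(spec.p1_tyr59_ring_angle,
                                                 180.0 - spec.p1_tyr59_ring_angle),
            })
            ledger["contacts"].append({
                "kind": "ch_pi", "partner_a": f"{spec.heavy_chain_id}/52/CD1",
                "partner_b": f"{spec.peptide_chain_id}/{p1_index + 1}/ring",
                "distance": d1, "angle": achieved_alpha,
            })
            ile_carbons = [atoms_by_residue[52][nm]
                           for nm in ("CB", "CG1", "CG2", "CD1")]
            p1_carbons = [p1_side[nm] for nm in ring_names + ["CB"]]
            min_cc = min(float(np.linalg.norm(p - q))
                         for p in p1_carbons for q in ile_carbons)
            if min_cc <= 4.5:
                ledger["contacts"].append({
                    "kind": "hydrophobic",
                    "partner_a": f"{spec.heavy_chain_id}/52",
                    "partner_b": f"{spec.peptide_chain_id}/{p1_index + 1}",
                    "distance": min_cc,
                })
        else:
            # Cbeta probe (alanine-like P1): two-sphere placement
            cb_p1 = _close_link(y59_center, cd1, d2, d1,
                                _unit(np.cross(cd1 - y59_center, y59_normal)))
            ca_p1 = cb_p1 + 1.53 * _unit(cb_p1 - 0.5 * (y59_center + cd1))
            p1_side = {"CB": cb_p1}
            ledger["descriptors"].update({"P1..I52": d1, "P1..Y59": d2})
    else:
        # no pocket residues: park the peptide above the chain midpoint
        mid = ca_path[L // 2]
        ca_p1 = mid + np.array([6.0, 0.0, 0.0])
        p1_side = {"CB": ca_p1 + 1.53 * np.array([1.0, 0.0, 0.0])}

    # peptide CA path through the planted P1 CA
    if has_pocket:
        prop = _unit(_unit(ca_p1 - pocket) + np.array([0.0, 0.0, 0.9]))
    else:
        prop = np.array([0.0, 0.0, 1.0])
    b1 = _any_perp(prop)
    b2 = np.cross(prop, b1)
    pep_ca = []
    for k, lab in enumerate(peptide_labels):
        step = k - p1_index
        wiggle = 0.45 * (math.sin(1.7 * step) * b1 + math.cos(1.3 * step) * b2)
        pep_ca.append(ca_p1 + 3.8 * step * prop + (wiggle if step != 0 else 0.0))
    pep_ca = np.asarray(pep_ca)
    pep_backbone = _build_backbone(pep_ca)

    for k, lab in enumerate(peptide_labels):
        res_name = spec.peptide_positions[lab]
        res_atoms = dict(pep_backbone[k])
        if lab == "P1":
            res_atoms.update(p1_side)
        elif res_name != "GLY":
            res_atoms["CB"] = _generic_cb(res_atoms["CA"], res_atoms["N"],
                                          res_atoms["C"])
            if res_name in ("TYR", "PHE"):
                ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
                d = _unit(res_atoms["CB"] - res_atoms["CA"])
                ring = _aromatic_ring(res_atoms["CB"], d, _any_perp(d),
                                      ring_names, bond=1.50)
                for nm in ring_names:
                    res_atoms[nm] = ring[nm]
                if res_name == "TYR":
                    res_atoms["OH"] = ring["CZ"] + 1.36 * _unit(
                        ring["CZ"] - ring["_center"])
            elif res_name == "CYS":
                res_atoms["SG"] = res_atoms["CB"] + 1.55 * _unit(
                    res_atoms["CB"] - res_atoms["CA"])
        peptide_atoms[lab] = res_atoms

    # ------------------------------------------------------------------
    # assemble the Structure
    # ------------------------------------------------------------------
    structure = Structure(id=f"SYNTH{spec.geometry_seed}")
    heavy = Chain(id=spec.heavy_chain_id)
    gap_numbers = {n for s_, e_ in spec.gap_ranges for n in range(s_, e_ + 1)}
    order = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}
    for i, n in enumerate(numbers):
        n = int(n)
        if n in gap_numbers:
            continue
        res = Residue(spec.heavy_chain_id, n, names[n])
        for atom_name in sorted(atoms_by_residue[n],
                                key=lambda a: (order.get(a, 9), a)):
            pos = atoms_by_residue[n][atom_name]
            res.atoms.append(Atom(atom_name, _element_of(atom_name), pos))
        heavy.residues.append(res)
    structure.chains.append(heavy)

    pep = Chain(id=spec.peptide_chain_id)
    for k, lab in enumerate(peptide_labels):
        res = Residue(spec.peptide_chain_id, k + 1, spec.peptide_positions[lab])
        for atom_name in sorted(peptide_atoms[lab],
                                key=lambda a: (order.get(a, 9), a)):
            res.atoms.append(Atom(atom_name, _element_of(atom_name),
                                  peptide_atoms[lab][atom_name]))
        pep.residues.append(res)
    structure.chains.append(pep)

    if spec.pocket_waters > 0 and names.get(59) == "TYR" and 59 not in gap_numbers:
        oh = atoms_by_residue[59]["OH"]
        wdir = _unit(ring_normals[59] + 0.4 * radial[58])
        wchain = Chain(id="W")
        prev = oh
        for k in range(spec.pocket_waters):
            pos = prev + 2.8 * wdir
            res = Residue("W", 1001 + k, "HOH", het=True)
            res.atoms.append(Atom("O", "O", pos))
            wchain.residues.append(res)
            ledger["contacts"].append({
                "kind": "hydrogen_bond",
                "partner_a": (f"{spec.heavy_chain_id}/59/OH" if k == 0
                              else f"W/{1000 + k}/O"),
                "partner_b": f"W/{1001 + k}/O",
                "distance": 2.8,
            })
            prev = pos
            wdir = _rotate(wdir, np.zeros(3), _any_perp(wdir), 35.0)
        structure.chains.append(wchain)

    peptide_map = PeptideMap(chain_id=spec.peptide_chain_id,
                             p1_number=p1_index + 1)

    # omega: measured as built, optionally rotated to a planted value
    try:
        omega0 = _measure_omega(structure, peptide_map, spec.heavy_chain_id)
    except Exception:
        omega0 = None
    if spec.omega_deg is not None:
        if omega0 is None:
            raise ValidationError("omega planting needs Cys76 CA, P7 CA, P1 CA, P1 N")
        _apply_omega(structure, peptide_map, spec.heavy_chain_id,
                     float(spec.omega_deg))
        omega0 = _measure_omega(structure, peptide_map, spec.heavy_chain_id)
    ledger["omega"] = omega0
    ledger["n_heavy_residues"] = len(heavy.residues)
    ledger["n_peptide_residues"] = len(pep.residues)
    return structure, ledger


def _element_of(atom_name: str) -> str:
    return {"N": "N", "O": "O", "S": "S"}.get(atom_name[0], "C")


def _omega_atoms(structure: Structure, peptide_map: PeptideMap,
                 heavy_chain_id: str, anchor_residue: int = 76):
    from mhcgroove.structure_io import select_atom
    a = select_atom(structure, heavy_chain_id, anchor_residue, "CA")
    b = select_atom(structure, peptide_map.chain_id, peptide_map.number("P7"), "CA")
    c = select_atom(structure, peptide_map.chain_id, peptide_map.number("P1"), "CA")
    d = select_atom(structure, peptide_map.chain_id, peptide_map.number("P1"), "N")
    return a, b, c, d


def _measure_omega(structure: Structure, peptide_map: PeptideMap,
                   heavy_chain_id: str) -> float:
    a, b, c, d = _omega_atoms(structure, peptide_map, heavy_chain_id)
    return dihedral(a.position, b.position, c.position, d.position)


def _apply_omega(structure: Structure, peptide_map: PeptideMap,
                 heavy_chain_id: str, target_deg: float) -> None:
    """Rotate the P1 amide nitrogen about the P7:CA - P1:CA axis until the
    omega torsion equals ``target_deg`` (modulo 360)."""
    a, b, c, d = _omega_atoms(structure, peptide_map, heavy_chain_id)
    axis_point, axis_dir = c.position, c.position - b.position
    current = dihedral(a.position, b.position, c.position, d.position)
    # sign calibration: a +1 degree probe tells which handedness the
    # rotation has on the torsion
    probe = _rotate(d.position, axis_point, axis_dir, 1.0)
    moved = dihedral(a.position, b.position, c.position, probe)
    delta_probe = (moved - current + 180.0) % 360.0 - 180.0
    sign = 1.0 if delta_probe > 0 else -1.0
    delta = (target_deg - current + 180.0) % 360.0 - 180.0
    d.position = _rotate(d.position, axis_point, axis_dir, sign * delta)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _schedule_array(schedule, n_frames: int, frame_interval: float) -> np.ndarray:
    if schedule is None:
        raise ValidationError("empty schedule")
    if isinstance(schedule, Mapping):
        kind = schedule.get("kind")
        if kind == "constant":
            return np.full(n_frames, float(schedule["value"]))
        if kind == "linear_ramp":
            return np.linspace(float(schedule["start"]), float(schedule["end"]),
                               n_frames)
        if kind == "piecewise":
            pts = sorted((float(t), float(v)) for t, v in schedule["points"])
            times = np.arange(n_frames) * frame_interval
            return np.interp(times, [p[0] for p in pts], [p[1] for p in pts])
        raise ValidationError(f"unknown schedule kind {kind!r}")
    arr = np.asarray(schedule, dtype=float)
    if arr.shape != (n_frames,):
        raise ValidationError(
            f"explicit schedule length {arr.shape} != n_frames {n_frames}")
    return arr


def make_trajectory(base: Structure, spec: TrajectorySpec,
                    peptide_map: PeptideMap | None = None,
                    heavy_chain_id: str = "A", anchor_residue: int = 76,
                    ) -> tuple["Trajectory", dict]:
    """Realise omega/descriptor schedules exactly, then add seeded noise.

    The omega schedule is applied by rotating the P1 amide nitrogen about
    the P7:CA - P1:CA axis, so the noise-free per-frame torsion equals the
    scheduled (unwrapped) value modulo 360.  Descriptor schedules translate
    the P1 side chain along the line to the fixed partner site.  Noise is
    isotropic per-atom Gaussian with per-residue sigmas, drawn from a
    named-stream generator so structure and noise draws are independently
    reproducible under one seed.
    """
    from mhcgroove.structure_io import Trajectory  # local to avoid cycle at import

    spec.validate()
    if peptide_map is None:
        peptide_map = PeptideMap(chain_id="C", p1_number=3)
    top = base.copy()
    n = spec.n_frames
    coords0 = top.coords()
    coords = np.broadcast_to(coords0, (n,) + coords0.shape).copy()
    probe_traj = Trajectory(top, coords0[None], spec.frame_interval)

    ledger: dict = {
        "seed": spec.seed,
        "n_frames": n,
        "frame_interval": spec.frame_interval,
        "total_time_ps": n * spec.frame_interval,
    }

    # --- omega schedule ------------------------------------------------
    if spec.omega_schedule is not None:
        targets = _schedule_array(spec.omega_schedule, n, spec.frame_interval)
        a, b, c, d = _omega_atoms(top, peptide_map, heavy_chain_id,
                                  anchor_residue)
        idx_n = probe_traj.atom_index(peptide_map.chain_id,
                                      peptide_map.number("P1"), "N")
        axis_point, axis_dir = c.position, c.position - b.position
        base_omega = dihedral(a.position, b.position, c.position, d.position)
        probe = _rotate(d.position, axis_point, axis_dir, 1.0)
        moved = dihedral(a.position, b.position, c.position, probe)
        sign = 1.0 if ((moved - base_omega + 180.0) % 360.0 - 180.0) > 0 else -1.0
        for f in range(n):
            delta = sign * (targets[f] - base_omega)
            coords[f, idx_n] = _rotate(d.position, axis_point, axis_dir, delta)
        ledger["omega_schedule"] = targets.tolist()
        ledger["omega_start"] = float(targets[0])
        ledger["omega_end"] = float(targets[-1])

    # --- descriptor schedules ------------------------------------------
    for name, sched in spec.descriptor_schedules.items():
        targets = _schedule_array(sched, n, spec.frame_interval)
        p1_number = peptide_map.number("P1")
        p1_res = top.chain(peptide_map.chain_id).residue(p1_number)
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        aromatic = all(p1_res.atom(nm) is not None for nm in ring_names)
        if aromatic:
            mobile_idx = [probe_traj.atom_index(peptide_map.chain_id, p1_number, nm)
                          for nm in ring_names]
        else:
            if p1_res.atom("CB") is None:
                raise ValidationError("descriptor schedule needs a P1 ring or CB")
            mobile_idx = [probe_traj.atom_index(peptide_map.chain_id, p1_number, "CB")]
        if name == "P1..Y59":
            tyr = top.chain(heavy_chain_id).residue(59)
            if tyr is None:
                raise ValidationError("descriptor schedule P1..Y59 needs residue 59")
            anchor = np.mean([tyr.atom(nm).position for nm in ring_names], axis=0)
        else:  # P1..I52
            ile = top.chain(heavy_chain_id).residue(52)
            if ile is None or ile.atom("CD1") is None:
                raise ValidationError("descriptor schedule P1..I52 needs Ile52 CD1")
            anchor = ile.atom("CD1").position
        probe_pt = coords0[mobile_idx].mean(axis=0)
        direction = _unit(probe_pt - anchor)
        current = float(np.linalg.norm(probe_pt - anchor))
        for f in range(n):
            coords[f, mobile_idx] += (targets[f] - current) * direction
        ledger.setdefault("descriptor_schedules", {})[name] = targets.tolist()

    # --- noise ----------------------------------------------------------
    sigma_map = spec.positional_noise_sigma
    if sigma_map is not None:
        per_atom = np.zeros(coords0.shape[0])
        if isinstance(sigma_map, (int, float)):
            per_atom[:] = float(sigma_map)
            ledger["noise_sigma"] = {"default": float(sigma_map)}
        else:
            default = float(sigma_map.get("default", 0.0))
            per_atom[:] = default
            recorded = {"default": default}
            for i, (ch, res, _a) in enumerate(top.iter_atoms()):
                key_t = (ch.id, res.number)
                if key_t in sigma_map:
                    per_atom[i] = float(sigma_map[key_t])
                    recorded[f"{ch.id}/{res.number}"] = per_atom[i]
                elif ch.id == heavy_chain_id and res.number in sigma_map:
                    per_atom[i] = float(sigma_map[res.number])
                    recorded[f"{ch.id}/{res.number}"] = per_atom[i]
            ledger["noise_sigma"] = recorded
        if np.any(per_atom < 0):
            raise ValidationError("noise sigmas must be >= 0")
        rng = np.random.default_rng([spec.seed, 202])
        coords += rng.normal(size=coords.shape) * per_atom[None, :, None]
    else:
        ledger["noise_sigma"] = {}

    return Trajectory(top, coords, spec.frame_interval), ledger


def sample_descriptor_population(distribution: Mapping, n: int, seed: int = 0
                                 ) -> np.ndarray:
    """Seeded draws from a Gaussian or Gaussian-mixture descriptor model,
    e.g. ``{"kind": "gaussian", "mean": 6.0, "sd": 0.5}`` or
    ``{"kind": "mixture", "components": [{"weight": 0.7, "mean": 5, "sd": 0.3},
    {"weight": 0.3, "mean": 10, "sd": 0.3}]}``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng([seed, 303])
    kind = distribution.get("kind")
    if kind == "gaussian":
        sd = float(distribution["sd"])
        if sd < 0:
            raise ValidationError("sd must be >= 0")
        return rng.normal(float(distribution["mean"]), sd, size=n)
    if kind == "mixture":
        comps = distribution.get("components", [])
        if not comps:
            raise ValidationError("mixture needs components")
        weights = np.array([float(c["weight"]) for c in comps])
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValidationError("mixture weights must be nonnegative, sum > 0")
        weights = weights / weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        means = np.array([float(c["mean"]) for c in comps])
        sds = np.array([float(c["sd"]) for c in comps])
        if np.any(sds < 0):
            raise ValidationError("sd must be >= 0")
        return rng.normal(means[which], sds[which])
    raise ValidationError(f"unknown distribution kind {kind!r}")
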