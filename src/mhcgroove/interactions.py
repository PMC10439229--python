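"""Interaction descriptors and contact-network extraction.

Implements the geometric probes used to characterise the N-terminus of the
MHC class I groove:

* distances between aromatic-ring geometrical centers (or the Cbeta atom
  when peptide position 1 is alanine) and named heavy-chain atoms,
* ring-plane orientation angles for pi-pi classification,
* the CH-pi criterion between an isoleucine Cdelta-H donor and an aromatic
  ring face (centroid distance plus C-H-centroid angle, with the hydrogen
  taken explicitly when present or constructed as an idealised methyl H),
* heavy-atom hydrogen-bond and side-chain hydrophobic contact networks.

Crystal structures carry no hydrogens, so hydrogen-bond detection is a
heavy-atom N/O distance criterion and the CH-pi hydrogen is constructed
geometrically unless an explicit one (e.g. from an MD frame) exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mhcgroove.errors import EvaluationError, GeometryError, SelectionError, ValidationError
from mhcgroove.geometry import angle_between, centroid, ring_normal
from mhcgroove.structure_io import PeptideMap, Residue, Structure, select_atom

__all__ = [
    "RING_ATOM_NAMES",
    "RingProbe",
    "AtomSite",
    "PeptideSite",
    "CHDonor",
    "InteractionDescriptor",
    "Contact",
    "evaluate_descriptor",
    "construct_cd_hydrogen",
    "classify_pi_pi",
    "detect_ch_pi",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_contacts",
    "contacts_to_tsv",
    "contacts_to_json",
]

# Six-membered aromatic ring definitions: the full ring for Phe/Tyr, the
# benzene ring of the indole for Trp.
RING_ATOM_NAMES = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

_CH_BOND = 1.09          # idealised aliphatic C-H bond length, Angstrom
_TETRAHEDRAL = 109.47    # ideal sp3 bond angle, degrees


@dataclass(frozen=True)
class RingProbe:
    """An aromatic ring addressed by residue; atom names default by residue
    identity (Phe/Tyr full ring, Trp benzene ring)."""

    chain_id: str
    residue_number: int
    ring_atom_names: tuple[str, ...] | None = None

    def names_for(self, residue: Residue) -> tuple[str, ...]:
        if self.ring_atom_names is not None:
            if len(self.ring_atom_names) < 3:
                raise ValidationError("a ring probe needs >= 3 atom names")
            return tuple(self.ring_atom_names)
        try:
            return tuple(RING_ATOM_NAMES[residue.name])
        except KeyError:
            raise ValidationError(
                f"no default ring definition for residue {residue.name}; "
                f"pass ring_atom_names explicitly") from None


@dataclass(frozen=True)
class AtomSite:
    chain_id: str
    residue_number: int
    atom_name: str


@dataclass(frozen=True)
class PeptideSite:
    """A symbolic peptide position (e.g. "P1") resolved through a
    :class:`PeptideMap`.

    The site kind is auto-selected by residue identity: an aromatic residue
    contributes its ring geometrical center, alanine its Cbeta atom.  This
    one rule encodes the dual distance definitions used for Phe- versus
    Ala-bearing peptides.
    """

    label: str = "P1"


@dataclass(frozen=True)
class CHDonor:
    """An isoleucine-like C-H donor: the Cdelta carbon plus its hydrogen."""

    chain_id: str
    residue_number: int
    carbon_name: str = "CD1"
    parent_name: str = "CG1"


Site = RingProbe | AtomSite | PeptideSite | CHDonor

METRICS = ("center_distance", "atom_distance", "ring_orientation_angle", "ch_pi_angle")


@dataclass(frozen=True)
class InteractionDescriptor:
    """A named geometric probe pair, e.g. ``P1..Y59`` or ``P1..I52``."""

    name: str
    site_a: Site
    site_b: Site
    metric: str

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.metric == "ring_orientation_angle":
            for s in (self.site_a, self.site_b):
                if not isinstance(s, (RingProbe, PeptideSite)):
                    raise ValidationError(
                        "ring_orientation_angle needs two ring-capable sites")
        if self.metric == "ch_pi_angle" and not isinstance(self.site_a, CHDonor):
            raise ValidationError("ch_pi_angle needs a CHDonor as site_a")


@dataclass
class Contact:
    kind: str                      # hydrogen_bond | hydrophobic | ch_pi | pi_pi
    partner_a: str
    partner_b: str
    distance: float
    angle: float | None = None
    pi_pi_class: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.distance <= 0:
            raise ValidationError("contact distance must be > 0")
        if (self.pi_pi_class is not None) != (self.kind == "pi_pi"):
            raise ValidationError("pi_pi_class present iff kind == 'pi_pi'")


# ---------------------------------------------------------------------------
# site resolution
# ---------------------------------------------------------------------------

def _get_residue(s: Structure, chain_id: str, number: int) -> Residue:
    chain = s.chain(chain_id)
    res = chain.residue(number) if chain is not None else None
    if res is None:
        raise EvaluationError(
            f"residue {chain_id}/{number} unresolvable (absent or disordered)",
            address=(chain_id, number, None))
    return res


def _ring_points(s: Structure, probe: RingProbe) -> np.ndarray:
    res = _get_residue(s, probe.chain_id, probe.residue_number)
    pts = []
    for name in probe.names_for(res):
        a = res.atom(name)
        if a is None:
            raise EvaluationError(
                f"ring atom {name} absent in {probe.chain_id}/{probe.residue_number} "
                f"({res.name})", address=(probe.chain_id, probe.residue_number, name))
        pts.append(a.position)
    return np.array(pts)


def resolve_ring(s: Structure, site: Site, peptide_map: PeptideMap | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a site to (ring centroid, ring normal)."""
    probe = site
    if isinstance(site, PeptideSite):
        probe = _peptide_probe(s, site, peptide_map)
        if not isinstance(probe, RingProbe):
            raise EvaluationError(
                f"peptide site {site.label} is not aromatic; no ring available")
    if not isinstance(probe, RingProbe):
        raise EvaluationError(f"site {site} does not define a ring")
    pts = _ring_points(s, probe)
    return centroid(pts), ring_normal(pts)


def _peptide_probe(s: Structure, site: PeptideSite,
                   peptide_map: PeptideMap | None) -> RingProbe | AtomSite:
    if peptide_map is None:
        raise EvaluationError("a PeptideMap is required to resolve peptide sites")
    number = peptide_map.number(site.label)
    res = _get_residue(s, peptide_map.chain_id, number)
    if res.name in RING_ATOM_NAMES:
        return RingProbe(peptide_map.chain_id, number)
    # alanine (and other non-aromatics) probe through Cbeta
    return AtomSite(peptide_map.chain_id, number, "CB")


def resolve_point(s: Structure, site: Site,
                  peptide_map: PeptideMap | None = None) -> np.ndarray:
    """Resolve a site to a single coordinate: ring centroid, atom position,
    or the (possibly constructed) donor hydrogen."""
    if isinstance(site, PeptideSite):
        site = _peptide_probe(s, site, peptide_map)
    if isinstance(site, RingProbe):
        return centroid(_ring_points(s, site))
    if isinstance(site, AtomSite):
        try:
            return select_atom(s, site.chain_id, site.residue_number,
                               site.atom_name).position
        except SelectionError as e:
            raise EvaluationError(
                str(e), address=(site.chain_id, site.residue_number,
                                 site.atom_name)) from e
    if isinstance(site, CHDonor):
        pos, _ = construct_cd_hydrogen(s, site.chain_id, site.residue_number,
                                       carbon_name=site.carbon_name,
                                       parent_name=site.parent_name)
        return pos
    raise EvaluationError(f"cannot resolve site of type {type(site).__name__}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def evaluate_descriptor(s: Structure, d: InteractionDescriptor,
                        peptide_map: PeptideMap | None = None) -> float:
    """Evaluate a descriptor on one structure; Angstrom for distances,
    degrees for angles.  Deterministic for fixed coordinates."""
    if d.metric in ("center_distance", "atom_distance"):
        pa = resolve_point(s, d.site_a, peptide_map)
        pb = resolve_point(s, d.site_b, peptide_map)
        return float(np.linalg.norm(pa - pb))
    if d.metric == "ring_orientation_angle":
        _, na = resolve_ring(s, d.site_a, peptide_map)
        _, nb = resolve_ring(s, d.site_b, peptide_map)
        return angle_between(na, nb, fold="fold_180")
    if d.metric == "ch_pi_angle":
        donor: CHDonor = d.site_a
        ring_c, _ = resolve_ring(s, d.site_b, peptide_map)
        cd = resolve_point(s, AtomSite(donor.chain_id, donor.residue_number,
                                       donor.carbon_name))
        h, _ = construct_cd_hydrogen(s, donor.chain_id, donor.residue_number,
                                     toward=ring_c, carbon_name=donor.carbon_name,
                                     parent_name=donor.parent_name)
        return angle_between(cd - h, ring_c - h, fold="none")
    raise ValidationError(f"unknown metric {d.metric!r}")


def _staggered_hydrogens(cd: np.ndarray, parent: np.ndarray,
                         ref: np.ndarray | None) -> list[np.ndarray]:
    """The three idealised methyl hydrogens on ``cd``, staggered about the
    parent->cd axis relative to a reference substituent on the parent."""
    axis = cd - parent
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise GeometryError("degenerate CG1-CD1 axis")
    axis = axis / norm
    # azimuth frame perpendicular to the axis
    if ref is not None:
        perp = (ref - parent) - np.dot(ref - parent, axis) * axis
    else:
        perp = np.zeros(3)
    if np.linalg.norm(perp) < 1e-9:
        # no usable reference substituent: any frame, still deterministic
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, axis)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = trial - np.dot(trial, axis) * axis
    e1 = perp / np.linalg.norm(perp)
    e2 = np.cross(axis, e1)
    cos_t = math.cos(math.radians(180.0 - _TETRAHEDRAL))
    sin_t = math.sin(math.radians(180.0 - _TETRAHEDRAL))
    out = []
    for phi_deg in (60.0, 180.0, 300.0):  # staggered w.r.t. the reference
        phi = math.radians(phi_deg)
        direction = (cos_t * axis
                     + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2))
        out.append(cd + _CH_BOND * direction)
    return out


def construct_cd_hydrogen(s: Structure, chain_id: str, residue_number: int,
                          toward: np.ndarray | None = None,
                          carbon_name: str = "CD1", parent_name: str = "CG1",
                          ) -> tuple[np.ndarray, str]:
    """Position of the hydrogen covalently bonded to an Ile Cdelta.

    If an explicit hydrogen within 1.2 Angstrom of the carbon exists (MD
    frames), it is returned flagged ``"explicit"``.  Otherwise an idealised
    methyl hydrogen is constructed 1.09 Angstrom from the carbon: of the
    three staggered positions about the parent-carbon axis, the one whose
    C-H-X angle toward ``toward`` (X, typically a ring centroid) deviates
    least from linearity is chosen; flagged ``"constructed"``.
    """
    res = _get_residue(s, chain_id, residue_number)
    cd_atom = res.atom(carbon_name)
    if cd_atom is None:
        raise EvaluationError(
            f"{carbon_name} absent in {chain_id}/{residue_number} ({res.name})",
            address=(chain_id, residue_number, carbon_name))
    cd = cd_atom.position
    # explicit hydrogen takes precedence: nearest H within covalent range
    best_h, best_d = None, 1.2
    for a in res.atoms:
        if a.element == "H" or a.name.startswith("H"):
            dist = float(np.linalg.norm(a.position - cd))
            if dist < best_d:
                best_h, best_d = a.position, dist
    if best_h is not None:
        return best_h.copy(), "explicit"
    parent_atom = res.atom(parent_name)
    if parent_atom is None:
        raise EvaluationError(
            f"{parent_name} absent in {chain_id}/{residue_number}; cannot "
            f"construct the methyl hydrogen",
            address=(chain_id, residue_number, parent_name))
    ref_atom = res.atom("CB")
    candidates = _staggered_hydrogens(cd, parent_atom.position,
                                      ref_atom.position if ref_atom else None)
    if toward is None:
        return candidates[1], "constructed"  # anti position, deterministic
    toward = np.asarray(toward, dtype=float)

    def linearity(h: np.ndarray) -> float:
        return abs(180.0 - angle_between(cd - h, toward - h))

    best = min(candidates, key=linearity)
    return best, "constructed"


def classify_pi_pi(theta: float, parallel_max: float = 30.0,
                   t_shaped_min: float = 60.0) -> str:
    """Classify a ring-orientation angle (degrees, [0, 180]).

    The angle is first folded to ``min(theta, 180 - theta)`` since antiparallel
    normals describe the same ring pairing; near-perpendicular rings are
    T-shaped, near-(anti)parallel ones stacking-like.  Boundaries default to
    30/60 degrees and are configurable.
    """
    if not 0.0 <= theta <= 180.0:
        raise GeometryError(f"ring orientation angle {theta} outside [0, 180]")
    if not 0.0 < parallel_max < t_shaped_min <= 90.0:
        raise ValidationError("require 0 < parallel_max < t_shaped_min <= 90")
    folded = min(theta, 180.0 - theta)
    if folded >= t_shaped_min:
        return "T_shaped"
    if folded <= parallel_max:
        return "parallel_like"
    return "intermediate"


def detect_ch_pi(s: Structure, donor: CHDonor, acceptor_ring: RingProbe,
                 max_distance: float = 5.5, min_angle: float = 120.0,
                 peptide_map: PeptideMap | None = None) -> Contact | None:
    """CH-pi contact test: ring-centroid-to-Cdelta distance <= ``max_distance``
    AND C-H-centroid angle >= ``min_angle``; ``None`` when either gate fails.

    Default thresholds (5.5 Angstrom, 120 degrees) bracket the ~5 Angstrom
    distance peaks and 120-150 degree angle range characteristic of stable
    CH-pi contacts in these complexes; both are configurable.
    """
    ring_c, _ = resolve_ring(s, acceptor_ring, peptide_map)
    cd = resolve_point(s, AtomSite(donor.chain_id, donor.residue_number,
                                   donor.carbon_name))
    dist = float(np.linalg.norm(ring_c - cd))
    if dist > max_distance:
        return None
    h, flag = construct_cd_hydrogen(s, donor.chain_id, donor.residue_number,
                                    toward=ring_c, carbon_name=donor.carbon_name,
                                    parent_name=donor.parent_name)
    ang = angle_between(cd - h, ring_c - h)
    if ang < min_angle:
        return None
    return Contact(kind="ch_pi",
                   partner_a=f"{donor.chain_id}/{donor.residue_number}/{donor.carbon_name}",
                   partner_b=f"{acceptor_ring.chain_id}/{acceptor_ring.residue_number}/ring",
                   distance=dist, angle=ang, extras={"hydrogen": flag})


def _region_residues(s: Structure, region: Sequence[tuple[str, int]]
                     ) -> list[Residue]:
    if not region:
        raise ValidationError("region must name at least one residue")
    out = []
    for chain_id, number in region:
        out.append(_get_residue(s, chain_id, number))
    return out


def _res_tag(r: Residue, a) -> str:
    return f"{r.chain_id}/{r.number}/{a.name}"


def detect_hydrogen_bonds(s: Structure, region: Sequence[tuple[str, int]],
                          include_waters: bool = False, d_max: float = 3.5,
                          ) -> list[Contact]:
    """Heavy-atom hydrogen bonds among N/O atoms of a residue region.

    All nitrogen/oxygen pairs across different residues at distance
    <= ``d_max`` are reported, excluding covalently related pairs (the
    backbone O(i)...N(i+1) 1-3 pair across a peptide bond).  Water oxygens
    of the whole structure join the donor/acceptor pool when
    ``include_waters`` is set.  No hydrogen positions are required.
    """
    residues = _region_residues(s, region)
    if include_waters:
        for c in s.chains:
            for r in c.residues:
                if r.is_water and r not in residues:
                    residues.append(r)
    pool: list[tuple[Residue, object]] = []
    for r in residues:
        for a in r.atoms:
            if a.element in ("N", "O") or (not a.element and a.name[:1] in "NO"):
                if r.is_water and a.element != "O" and a.name[:1] != "O":
                    continue
                pool.append((r, a))
    contacts: list[Contact] = []
    for i in range(len(pool)):
        ri, ai = pool[i]
        for j in range(i + 1, len(pool)):
            rj, aj = pool[j]
            if ri is rj:
                continue
            # exclude the 1-3 backbone pair O(i)..N(i+1) through the peptide bond
            if ri.chain_id == rj.chain_id and abs(ri.number - rj.number) == 1:
                lo, hi = (ri, ai), (rj, aj)
                if ri.number > rj.number:
                    lo, hi = hi, lo
                if lo[1].name == "O" and hi[1].name == "N":
                    continue
            dist = float(np.linalg.norm(ai.position - aj.position))
            if dist <= d_max:
                contacts.append(Contact(kind="hydrogen_bond",
                                        partner_a=_res_tag(ri, ai),
                                        partner_b=_res_tag(rj, aj),
                                        distance=dist))
    contacts.sort(key=lambda c: (c.partner_a, c.partner_b))
    return contacts


def detect_hydrophobic_contacts(s: Structure, region: Sequence[tuple[str, int]],
                                d_max: float = 4.5) -> list[Contact]:
    """Side-chain carbon-carbon contacts across residues of a region,
    deduplicated to one contact per residue pair at the minimum distance."""
    residues = _region_residues(s, region)
    best: dict[tuple, Contact] = {}
    for i in range(len(residues)):
        ri = residues[i]
        ci = [a for a in ri.atoms
              if a.name not in BACKBONE_NAMES and (a.element == "C" or
                                                   (not a.element and a.name[:1] == "C"))]
        for j in range(i + 1, len(residues)):
            rj = residues[j]
            cj = [a for a in rj.atoms
                  if a.name not in BACKBONE_NAMES and (a.element == "C" or
                                                       (not a.element and a.name[:1] == "C"))]
            for ai in ci:
                for aj in cj:
                    dist = float(np.linalg.norm(ai.position - aj.position))
                    if dist <= d_max:
                        key = tuple(sorted([(ri.chain_id, ri.number),
                                            (rj.chain_id, rj.number)]))
                        if key not in best or dist < best[key].distance:
                            best[key] = Contact(kind="hydrophobic",
                                                partner_a=_res_tag(ri, ai),
                                                partner_b=_res_tag(rj, aj),
                                                distance=dist)
    return sorted(best.values(), key=lambda c: (c.partner_a, c.partner_b))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def contacts_to_tsv(contacts: Sequence[Contact]) -> str:
    lines = ["kind\tpartner_a\tpartner_b\tdistance\tangle\tclass"]
    for c in contacts:
        ang = f"{c.angle:.2f}" if c.angle is not None else ""
        cls = c.pi_pi_class or ""
        lines.append(f"{c.kind}\t{c.partner_a}\t{c.partner_b}\t"
                     f"{c.distance:.3f}\t{ang}\t{cls}")
    return "\n".join(lines) + "\n"


def contacts_to_json(contacts: Sequence[Contact]) -> str:
    return json.dumps([{
        "kind": c.kind, "partner_a": c.partner_a, "partner_b": c.partner_b,
        "distance": c.distance, "angle": c.angle, "pi_pi_class": c.pi_pi_class,
        **({"extras": c.extras} if c.extras else {}),
    } for c in contacts], indent=2)
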