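"""Structure and trajectory I/O with author-number addressing.

Coordinates are read and written through :mod:`gemmi`; the in-memory model
is a small chain -> residue -> atom hierarchy addressed exclusively by the
author numbering of the deposited entry (no renumbering).  Multi-model PDB
files are the carrier for conformational ensembles: the first model is used
for crystal structures (:func:`read_structure`) and all models for
trajectories (:func:`read_trajectory`); the distinction is made by the
operation called, never by sniffing the file.

Missing (crystallographically disordered) residues are detected as author
numbers absent from a chain relative to an expected range; electron-density
levels are not representable from coordinates alone, so disorder is
reported purely as residue absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from mhcgroove.errors import (
    FormatError,
    ParseError,
    SelectionError,
    SerializationError,
    StructuralError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PeptideMap",
    "GapReport",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "detect_missing_residues",
    "select_atom",
]

# Water residue names excluded from chain-level analyses unless asked for.
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# PDB fixed-width coordinate field %8.3f
_COORD_MIN, _COORD_MAX = -999.999, 9999.999


@dataclass
class Atom:
    """A single atom record after alternate-location resolution."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    temperature_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    het: bool = False

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water]


@dataclass
class Structure:
    """Hierarchical chain -> residue -> atom coordinate model."""

    id: str = ""
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """Flat (n_atoms, 3) coordinate array in iteration order."""
        n = self.atom_count
        out = np.empty((n, 3))
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            out[i] = a.position
        return out

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            a.position = coords[i].copy()

    def copy(self) -> "Structure":
        new = Structure(id=self.id)
        for c in self.chains:
            nc = Chain(id=c.id)
            for r in c.residues:
                nr = Residue(r.chain_id, r.number, r.name,
                             insertion_code=r.insertion_code, het=r.het)
                nr.atoms = [Atom(a.name, a.element, a.position.copy(),
                                 a.occupancy, a.temperature_factor, a.altloc)
                            for a in r.atoms]
                nc.residues.append(nr)
            new.chains.append(nc)
        return new

    @property
    def resolved_ranges(self) -> dict[str, list[tuple[int, int]]]:
        """Per chain, intervals [first, last] of consecutively present
        author numbers (waters excluded)."""
        ranges: dict[str, list[tuple[int, int]]] = {}
        for c in self.chains:
            numbers = sorted({r.number for r in c.polymer_residues()})
            ivals: list[tuple[int, int]] = []
            for n in numbers:
                if ivals and n == ivals[-1][1] + 1:
                    ivals[-1] = (ivals[-1][0], n)
                else:
                    ivals.append((n, n))
            ranges[c.id] = ivals
        return ranges


@dataclass
class PeptideMap:
    """Symbolic peptide-position labels (P-2 ... P8) over author numbers.

    P1 is the canonical N-terminal groove position; positive labels run
    toward the C-terminus (P2 = P1 + 1 residue) and negative labels are
    N-terminal extension positions (P-1 is one residue before P1).  There
    is no P0, so consecutive labels map to consecutive author numbers.
    """

    chain_id: str
    p1_number: int

    def number(self, label: str) -> int:
        if not label.startswith("P"):
            raise ValidationError(f"peptide position label {label!r} must start with 'P'")
        try:
            k = int(label[1:])
        except ValueError as e:
            raise ValidationError(f"bad peptide position label {label!r}") from e
        if k == 0:
            raise ValidationError("there is no peptide position P0")
        return self.p1_number + (k - 1 if k > 0 else k)

    def offsets(self, labels: Iterable[str] = None) -> dict[str, int]:
        labels = labels or [f"P{k}" for k in (-2, -1, 1, 2, 3, 4, 5, 6, 7, 8)]
        return {lab: self.number(lab) for lab in labels}


@dataclass
class GapReport:
    """Missing-residue stretches of one chain against an expected range."""

    chain_id: str
    expected_range: tuple[int, int]
    # (start_number, end_number, count, start_residue_name, end_residue_name)
    gaps: list[tuple[int, int, int, str, str]] = field(default_factory=list)

    @property
    def total_missing(self) -> int:
        return sum(g[2] for g in self.gaps)

    def to_tsv(self) -> str:
        lines = ["chain\tstart\tend\tcount\tstart_name\tend_name"]
        for s, e, n, sn, en in self.gaps:
            lines.append(f"{self.chain_id}\t{s}\t{e}\t{n}\t{sn}\t{en}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "chain_id": self.chain_id,
            "expected_range": list(self.expected_range),
            "gaps": [{"start": s, "end": e, "count": n,
                      "start_name": sn, "end_name": en}
                     for s, e, n, sn, en in self.gaps],
        }, indent=2)


class Trajectory:
    """An ordered stack of topology-identical coordinate frames.

    Coordinates are stored as one ``(n_frames, n_atoms, 3)`` array over a
    shared topology; :meth:`frame` materialises a :class:`Structure`
    snapshot on demand.  ``frame_interval`` is the saving interval in ps.
    """

    def __init__(self, topology: Structure, coords: np.ndarray,
                 frame_interval: float, start_time: float = 0.0):
        if frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0 ps")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != topology.atom_count:
            raise StructuralError(
                f"coordinate array has {coords.shape[1]} atoms, topology has "
                f"{topology.atom_count}")
        self.topology = topology
        self.coords = coords
        self.frame_interval = float(frame_interval)
        self.start_time = float(start_time)
        self._index: dict[tuple[str, int, str, str], int] | None = None

    # -- addressing -------------------------------------------------------
    def _build_index(self) -> dict[tuple[str, int, str, str], int]:
        if self._index is None:
            self._index = {}
            for i, (c, r, a) in enumerate(self.topology.iter_atoms()):
                self._index[(c.id, r.number, r.insertion_code, a.name)] = i
        return self._index

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str,
                   insertion_code: str = "") -> int:
        idx = self._build_index()
        key = (chain_id, residue_number, insertion_code, atom_name)
        if key not in idx:
            # reuse select_atom for a precise error message
            select_atom(self.topology, chain_id, residue_number, atom_name,
                        insertion_code)
            raise SelectionError(f"atom {key} not indexed", reason="atom_absent")
        return idx[key]

    # -- frames -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return self.start_time + self.frame_interval * np.arange(self.n_frames)

    @property
    def total_time(self) -> float:
        """Total simulated time covered, n_frames * frame_interval (ps)."""
        return self.n_frames * self.frame_interval

    def frame(self, i: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.coords[i])
        return s

    @property
    def frames(self) -> list[Structure]:
        return [self.frame(i) for i in range(self.n_frames)]

    @classmethod
    def from_frames(cls, frames: Sequence[Structure], frame_interval: float,
                    start_time: float = 0.0) -> "Trajectory":
        if not frames:
            raise ValidationError("a trajectory needs at least one frame")
        top = frames[0]
        for k, f in enumerate(frames[1:], start=2):
            _check_same_topology(top, f, k)
        coords = np.stack([f.coords() for f in frames])
        return cls(frames[0].copy(), coords, frame_interval, start_time)


def _check_same_topology(a: Structure, b: Structure, model_number: int) -> None:
    sig_a = [(c.id, r.number, r.insertion_code, r.name, tuple(x.name for x in r.atoms))
             for c in a.chains for r in c.residues]
    sig_b = [(c.id, r.number, r.insertion_code, r.name, tuple(x.name for x in r.atoms))
             for c in b.chains for r in c.residues]
    if sig_a != sig_b:
        for ra, rb in zip(sig_a, sig_b):
            if ra != rb:
                raise StructuralError(
                    f"model {model_number}: topology diverges at residue "
                    f"{ra[0]}/{ra[1]}{ra[2]} ({ra[3]}) vs {rb[0]}/{rb[1]}{rb[2]} ({rb[3]})")
        raise StructuralError(
            f"model {model_number}: models differ in residue count "
            f"({len(sig_a)} vs {len(sig_b)})")


# ---------------------------------------------------------------------------
# gemmi conversion
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep, per atom name, the highest-occupancy alternate location
    (ties broken by the alphabetically first altloc id)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
        picked.append(best)
    return picked


def _convert_model(model: gemmi.Model, structure_id: str) -> Structure:
    s = Structure(id=structure_id)
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            het = gres.het_flag == "H"
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                name=gres.name,
                insertion_code=(gres.seqid.icode or "").strip(),
                het=het,
            )
            for ga in _resolve_altlocs(list(gres)):
                res.atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    temperature_factor=ga.b_iso,
                    altloc=(ga.altloc or "").strip(),
                ))
            chain.residues.append(res)
        s.chains.append(chain)
    return s


def _to_gemmi(structures: Sequence[Structure], structure_id: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure_id
    for mi, s in enumerate(structures, start=1):
        model = gemmi.Model(mi)
        for c in s.chains:
            gchain = gemmi.Chain(c.id)
            for r in c.residues:
                gres = gemmi.Residue()
                gres.name = r.name
                gres.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
                gres.het_flag = "H" if r.het else "A"
                for a in r.atoms:
                    if len(a.name) > 4:
                        raise SerializationError(
                            f"atom name {a.name!r} exceeds 4 characters")
                    if np.any(a.position < _COORD_MIN) or np.any(a.position > _COORD_MAX):
                        raise SerializationError(
                            f"coordinate of {c.id}/{r.number}/{a.name} overflows "
                            f"the fixed-width PDB field: {a.position}")
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element or "X")
                    ga.pos = gemmi.Position(*a.position)
                    ga.occ = a.occupancy
                    ga.b_iso = a.temperature_factor
                    ga.altloc = a.altloc or "\0"
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            model.add_chain(gchain)
        st.add_model(model)
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _read_gemmi(path: str | Path, format: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        return gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"cannot parse {path}: {e}") from e


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read the first model of a PDB/mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties to the alphabetically first altloc).  Waters and other HETATM
    records are retained with ``Residue.het``/``is_water`` flags; chain
    level analyses exclude them by default.
    """
    gst = _read_gemmi(path, format)
    if len(gst) == 0:
        raise ParseError(f"{path}: no coordinate models found")
    return _convert_model(gst[0], structure_id=gst.name or Path(path).stem)


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as fixed-width PDB (the only output format)."""
    if format != "pdb":
        raise FormatError(f"unsupported output format {format!r}")
    st = _to_gemmi([s], s.id or "XXXX")
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def read_trajectory(path: str | Path, frame_interval: float,
                    start_time: float = 0.0, format: str = "auto") -> Trajectory:
    """Read a multi-model PDB file as an ordered trajectory.

    Frames are ordered by MODEL number and verified to share one topology;
    the first divergent residue is named in the error otherwise.
    """
    gst = _read_gemmi(path, format)
    if len(gst) == 0:
        raise ParseError(f"{path}: no MODEL blocks found")
    frames = [_convert_model(m, structure_id=gst.name or Path(path).stem)
              for m in gst]
    return Trajectory.from_frames(frames, frame_interval, start_time)


def write_trajectory(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a MODEL/ENDMDL multi-model PDB file."""
    st = _to_gemmi(t.frames, t.topology.id or "TRAJ")
    Path(path).write_text(st.make_pdb_string())


def detect_missing_residues(s: Structure, chain_id: str,
                            expected_range: tuple[int, int],
                            reference_sequence: str | None = None,
                            ) -> GapReport:
    """Report stretches of author numbers absent from a chain.

    ``expected_range`` is the inclusive [first, last] author-number span the
    chain should cover.  Flanking residue names of each gap are read from
    ``reference_sequence`` (a one-letter string where position ``i`` holds
    the residue with author number ``i``, 1-based); the residues themselves
    are absent so their names cannot be read from the coordinates.  Without
    a reference the names are reported as ``"UNK"``.
    """
    first, last = expected_range
    if first > last:
        raise ValidationError(f"expected_range {expected_range} has first > last")
    chain = s.chain(chain_id)
    if chain is None:
        raise SelectionError(f"chain {chain_id!r} absent from structure {s.id!r}",
                             reason="chain_absent")
    present = {r.number for r in chain.polymer_residues()}

    def name_of(num: int) -> str:
        if reference_sequence is not None and 1 <= num <= len(reference_sequence):
            return _AA_1TO3.get(reference_sequence[num - 1].upper(), "UNK")
        return "UNK"

    gaps: list[tuple[int, int, int, str, str]] = []
    run_start = None
    for n in range(first, last + 1):
        if n not in present:
            if run_start is None:
                run_start = n
        else:
            if run_start is not None:
                gaps.append((run_start, n - 1, n - run_start,
                             name_of(run_start), name_of(n - 1)))
                run_start = None
    if run_start is not None:
        gaps.append((run_start, last, last - run_start + 1,
                     name_of(run_start), name_of(last)))
    return GapReport(chain_id=chain_id, expected_range=(first, last), gaps=gaps)


def select_atom(s: Structure, chain_id: str, residue_number: int,
                atom_name: str, insertion_code: str = "") -> Atom:
    """Return the unique (altloc-resolved) atom at an author-number address.

    Raises :class:`SelectionError` whose ``reason`` distinguishes a residue
    missing from the model (e.g. crystallographically disordered) from an
    atom name absent within a present residue.
    """
    chain = s.chain(chain_id)
    if chain is None:
        raise SelectionError(f"chain {chain_id!r} absent", reason="chain_absent")
    res = chain.residue(residue_number, insertion_code)
    if res is None:
        raise SelectionError(
            f"residue {chain_id}/{residue_number}{insertion_code} absent "
            f"(unmodelled or out of range)", reason="residue_absent")
    atom = res.atom(atom_name)
    if atom is None:
        raise SelectionError(
            f"atom {atom_name!r} absent in residue {chain_id}/{residue_number} "
            f"({res.name})", reason="atom_absent")
    return atom
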