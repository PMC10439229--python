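"""Trajectory statistics: RMSF, descriptor distributions, omega traces.

The omega dihedral (Cys76:CA - P7:CA - P1:CA - P1:N) tracks the rotation of
the peptide N-terminal amino group in pocket A.  Raw per-frame torsions live
in (-180, 180]; the unwrapping rule requires the rotation between two
neighbouring frames to be less than 180 degrees and otherwise shifts the
next value by multiples of 360, so full rotations accumulate instead of
wrapping.  Traces are then smoothed with a centered sliding-window average
(default 10 ns) to suppress thermal fluctuation before rotation-event
detection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mhcgroove.errors import EvaluationError, StructuralError, ValidationError
from mhcgroove.geometry import dihedral_series, kabsch
from mhcgroove.interactions import (
    AtomSite,
    InteractionDescriptor,
    PeptideSite,
    RingProbe,
    evaluate_descriptor,
)
from mhcgroove.structure_io import PeptideMap, Trajectory

__all__ = [
    "RmsfProfile",
    "DistributionSummary",
    "DihedralTrace",
    "RotationVerdict",
    "compute_rmsf",
    "descriptor_series",
    "summarize_distribution",
    "unwrap_dihedral",
    "smooth_trace",
    "omega_trace",
    "detect_canonical_rotation",
]


@dataclass
class RmsfProfile:
    """Per-residue root mean square fluctuation along one chain."""

    chain_id: str
    entries: list[tuple[int, float]]  # (author residue number, rmsf in Angstrom)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([n for n, _ in self.entries])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def argmax_residue(self) -> int:
        return self.entries[int(np.argmax(self.values))][0]

    def to_tsv(self) -> str:
        lines = ["residue\trmsf"]
        lines += [f"{n}\t{v:.4f}" for n, v in self.entries]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({"chain_id": self.chain_id,
                           "entries": [[n, v] for n, v in self.entries]}, indent=2)


@dataclass
class DistributionSummary:
    """Normalised histogram with modal-bin peak and IQR width."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    peak_location: float
    width_metric: float  # empirical interquartile range

    def to_json(self) -> str:
        return json.dumps({
            "bin_edges": self.bin_edges.tolist(),
            "probabilities": self.probabilities.tolist(),
            "peak_location": self.peak_location,
            "iqr": self.width_metric,
        }, indent=2)


@dataclass
class DihedralTrace:
    """Raw/unwrapped/smoothed omega series over frame times (ps)."""

    times: np.ndarray
    omega_raw: np.ndarray
    omega_unwrapped: np.ndarray
    omega_smoothed: np.ndarray
    window: float  # smoothing window, ns

    def to_tsv(self) -> str:
        lines = ["time_ps\traw\tunwrapped\tsmoothed"]
        for t, r, u, sm in zip(self.times, self.omega_raw,
                               self.omega_unwrapped, self.omega_smoothed):
            lines.append(f"{t:.1f}\t{r:.3f}\t{u:.3f}\t{sm:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class RotationVerdict:
    reached: bool
    first_time: float | None  # ps, start of the first qualifying dwell
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def compute_rmsf(t: Trajectory, chain_id: str, atom_name: str = "CA",
                 align_selection: Sequence[tuple[str, int, str]] | None = None,
                 n_passes: int = 2) -> RmsfProfile:
    """Per-residue RMSF of one atom type after rigid alignment.

    Each frame is Kabsch-fit onto a reference over ``align_selection``
    (default: all CA atoms of ``chain_id``); the reference is iterated to
    the time-average structure (``n_passes`` alignment passes).  The RMSF of
    a residue is the root mean squared displacement of its chosen atom from
    its time-average position.
    """
    if t.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    chain = t.topology.chain(chain_id)
    if chain is None:
        raise StructuralError(f"chain {chain_id!r} absent from trajectory topology")
    target: list[tuple[int, int]] = []  # (residue number, flat atom index)
    for r in chain.polymer_residues():
        if r.atom(atom_name) is not None:
            target.append((r.number, t.atom_index(chain_id, r.number, atom_name,
                                                  r.insertion_code)))
    if not target:
        raise StructuralError(f"no {atom_name!r} atoms found in chain {chain_id!r}")
    if align_selection is None:
        sel_idx = [i for _, i in target] if atom_name == "CA" else [
            t.atom_index(chain_id, r.number, "CA", r.insertion_code)
            for r in chain.polymer_residues() if r.atom("CA") is not None]
    else:
        sel_idx = [t.atom_index(c, n, a) for c, n, a in align_selection]
    if len(sel_idx) < 3:
        raise StructuralError("alignment selection needs >= 3 atoms")

    coords = t.coords
    aligned = coords.copy()
    ref = coords[0, sel_idx]
    for _ in range(max(1, n_passes)):
        for f in range(t.n_frames):
            sup = kabsch(coords[f, sel_idx], ref)
            aligned[f] = sup.apply(coords[f])
        ref = aligned[:, sel_idx].mean(axis=0)

    entries = []
    for num, idx in target:
        traj_xyz = aligned[:, idx, :]
        mean_pos = traj_xyz.mean(axis=0)
        rmsf = float(np.sqrt(np.mean(np.sum((traj_xyz - mean_pos) ** 2, axis=1))))
        entries.append((num, rmsf))
    return RmsfProfile(chain_id=chain_id, entries=entries)


# ---------------------------------------------------------------------------
# descriptor time series
# ---------------------------------------------------------------------------

def _site_point_series(t: Trajectory, site, peptide_map) -> np.ndarray:
    """(n_frames, 3) series of the point a site resolves to; vectorised for
    the common site kinds."""
    top = t.topology
    if isinstance(site, PeptideSite):
        from mhcgroove.interactions import _peptide_probe
        site = _peptide_probe(top, site, peptide_map)
    if isinstance(site, AtomSite):
        idx = t.atom_index(site.chain_id, site.residue_number, site.atom_name)
        return t.coords[:, idx, :]
    if isinstance(site, RingProbe):
        res = top.chain(site.chain_id).residue(site.residue_number)
        if res is None:
            raise EvaluationError(f"residue {site.chain_id}/{site.residue_number} absent",
                                  address=(site.chain_id, site.residue_number, None))
        idx = [t.atom_index(site.chain_id, site.residue_number, name)
               for name in site.names_for(res)]
        return t.coords[:, idx, :].mean(axis=1)
    raise EvaluationError(f"unsupported site type {type(site).__name__} in series")


def descriptor_series(t: Trajectory, d: InteractionDescriptor,
                      peptide_map: PeptideMap | None = None,
                      discard_initial: float = 0.0) -> np.ndarray:
    """Evaluate one descriptor on every frame (order-preserving).

    ``discard_initial`` (ps) drops an initial equilibration stretch before
    evaluation; default 0 analyses the whole ensemble as given.
    """
    start_frame = int(np.ceil(discard_initial / t.frame_interval)) if discard_initial else 0
    if start_frame >= t.n_frames:
        raise ValidationError("discard_initial removes every frame")
    if d.metric in ("center_distance", "atom_distance"):
        try:
            pa = _site_point_series(t, d.site_a, peptide_map)
            pb = _site_point_series(t, d.site_b, peptide_map)
        except EvaluationError:
            raise
        return np.linalg.norm(pa - pb, axis=1)[start_frame:]
    # angle metrics need per-frame plane fits / hydrogen construction
    out = np.empty(t.n_frames - start_frame)
    for k, f in enumerate(range(start_frame, t.n_frames)):
        try:
            out[k] = evaluate_descriptor(t.frame(f), d, peptide_map)
        except EvaluationError as e:
            raise EvaluationError(f"frame {f}: {e}", address=e.address) from e
    return out


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def summarize_distribution(series: Sequence[float], bin_width: float = 0.2
                           ) -> DistributionSummary:
    """Histogram a scalar series into fixed-width bins (default 0.2, meant
    for Angstrom-valued series; use e.g. 5.0 for angles in degrees).

    Probabilities are normalised to unit total; the peak is the center of
    the modal bin with ties resolved toward the lowest value; the width
    metric is the empirical interquartile range of the raw samples.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarise an empty series")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((x.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    probs = counts / counts.sum()
    peak_bin = int(np.argmax(probs))  # argmax takes the first (lowest) tie
    peak = float(edges[peak_bin] + bin_width / 2)
    q75, q25 = np.percentile(x, [75, 25])
    return DistributionSummary(bin_edges=edges, probabilities=probs,
                               peak_location=peak, width_metric=float(q75 - q25))


# ---------------------------------------------------------------------------
# omega trace machinery
# ---------------------------------------------------------------------------

def unwrap_dihedral(omega_raw: Sequence[float]) -> np.ndarray:
    """Lift a principal-range (-180, 180] torsion series to a continuous one.

    The first value is kept; each subsequent value is shifted by the unique
    multiple of 360 degrees making the step magnitude < 180, so the output
    is congruent to the input modulo 360 elementwise.  A step of exactly
    180 degrees is resolved toward the positive shift.
    """
    raw = np.asarray(omega_raw, dtype=float)
    if raw.size == 0:
        return raw.copy()
    steps = np.diff(raw)
    # principal-value the steps into (-180, 180]
    folded = np.mod(steps + 180.0, 360.0) - 180.0
    folded[folded == -180.0] = 180.0  # documented tie-break
    # integer shift counts keep the output exactly congruent to the input
    shifts = np.rint((folded - steps) / 360.0)
    out = raw.copy()
    out[1:] += 360.0 * np.cumsum(shifts)
    return out


def smooth_trace(series: Sequence[float], times: Sequence[float],
                 window: float = 10.0) -> np.ndarray:
    """Centered moving average over all samples within +-window/2 (window in
    ns, times in ps); edges use the truncated window, so the trace keeps its
    length.  A window shorter than one frame interval returns the input with
    a warning."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if window <= 0:
        raise ValidationError("smoothing window must be > 0 ns")
    if y.shape != t.shape:
        raise ValidationError("series and times must have equal length")
    if y.size < 2:
        return y.copy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("smooth_trace requires uniformly spaced times")
    half_ps = window * 1000.0 / 2.0
    hw = int(np.floor(half_ps / dt[0] + 1e-9))
    if hw < 1 and window * 1000.0 < dt[0]:
        warnings.warn("smoothing window shorter than the frame interval; "
                      "returning the series unchanged", stacklevel=2)
        return y.copy()
    csum = np.concatenate([[0.0], np.cumsum(y)])
    n = y.size
    idx = np.arange(n)
    lo = np.maximum(idx - hw, 0)
    hi = np.minimum(idx + hw, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def omega_trace(t: Trajectory, peptide_map: PeptideMap, heavy_chain_id: str,
                window: float = 10.0, anchor_residue: int = 76,
                ) -> DihedralTrace:
    """Per-frame omega = torsion(anchor:CA, P7:CA, P1:CA, P1:N), unwrapped
    and smoothed.  ``anchor_residue`` defaults to the heavy-chain Cys76 that
    tethers the peptide."""
    try:
        ia = t.atom_index(heavy_chain_id, anchor_residue, "CA")
        ib = t.atom_index(peptide_map.chain_id, peptide_map.number("P7"), "CA")
        ic = t.atom_index(peptide_map.chain_id, peptide_map.number("P1"), "CA")
        id_ = t.atom_index(peptide_map.chain_id, peptide_map.number("P1"), "N")
    except Exception as e:
        raise EvaluationError(f"omega atoms unresolvable: {e}") from e
    raw = dihedral_series(t.coords[:, ia], t.coords[:, ib],
                          t.coords[:, ic], t.coords[:, id_])
    unwrapped = unwrap_dihedral(raw)
    smoothed = smooth_trace(unwrapped, t.times, window=window)
    return DihedralTrace(times=t.times, omega_raw=raw,
                         omega_unwrapped=unwrapped, omega_smoothed=smoothed,
                         window=window)


def detect_canonical_rotation(trace: DihedralTrace, canonical: float = 97.0,
                              tolerance: float = 45.0, dwell: float = 50.0,
                              ) -> RotationVerdict:
    """Has the amino group rotated to the canonical 'down' orientation?

    The smoothed trace is reduced modulo 360 into (-180, 180] (so e.g.
    460 and -260 are equivalent to 100) and the verdict is positive iff the
    reduced trace stays within ``canonical +- tolerance`` continuously for at
    least ``dwell`` ns; ``first_time`` is the start (ps) of the first such
    dwell.  The default 97 +- 45 degree band is centred between the printed
    canonical 8mer values (96, 98) and wide enough to cover their 100-degree
    equivalents without reaching the 'up' orientations near -70 to -110.
    """
    y = trace.omega_smoothed
    if y.size == 0:
        return RotationVerdict(reached=False, first_time=None)
    diff = np.mod(y - canonical + 180.0, 360.0) - 180.0
    inside = np.abs(diff) <= tolerance
    dt = trace.times[1] - trace.times[0] if y.size > 1 else 0.0
    dwell_ps = dwell * 1000.0
    start = None
    for i, ok in enumerate(inside):
        if ok and start is None:
            start = i
        span_end = i if ok else i - 1
        if start is not None and (not ok or i == len(inside) - 1):
            if (span_end - start) * dt >= dwell_ps:
                return RotationVerdict(reached=True,
                                       first_time=float(trace.times[start]))
            if not ok:
                start = None
    return RotationVerdict(reached=False, first_time=None)
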