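# Methods

This note documents the models, conventions and numerical choices behind
`mhcgroove`, and what its synthetic fixtures do and do not establish about
real data.

## Coordinate model and addressing

Structures are hierarchies of chains → residues → atoms read through gemmi.
Author numbering as deposited is the only addressing scheme; the package
never renumbers. Peptide positions are symbolic labels `P-2 … P8` resolved
through a `PeptideMap` (`P1` = the canonical N-terminal groove position;
there is no `P0`, so consecutive labels map to consecutive author numbers).
Alternate locations are resolved at read time to the highest-occupancy
conformer, ties broken by the alphabetically first altloc — deterministic
and conventional. Waters and other HETATM records are kept but flagged, and
excluded from chain-level analyses unless explicitly included (hydrogen-bond
networks). The first model of a file is a crystal structure; all models are
a trajectory — the distinction is the operation called
(`read_structure` vs `read_trajectory`), never file sniffing.

Missing (crystallographically disordered) residues are reported as author
numbers absent from a chain within an expected range. Electron-density
levels cannot be reconstructed from coordinates, so disorder is residue
absence, nothing finer. A gap's flanking residue names cannot be read from
records that do not exist; they come from an optional reference sequence
(one-letter string indexed by author number) and are `UNK` without one.

## Geometry

- **Ring centroids** are arithmetic means of the ring atom coordinates.
  Ring atom sets: Phe/Tyr `CG CD1 CD2 CE1 CE2 CZ`; Trp uses its benzene
  ring `CD2 CE2 CE3 CZ2 CZ3 CH2`.
- **Ring normals** are the smallest-variance principal axis of the centered
  ring coordinates (best-fit plane; robust to slight non-planarity). A
  normal's sign is intrinsically ambiguous; the package orients it so its
  first non-zero component is nonnegative. Consequently an inter-ring angle
  θ and 180° − θ describe the same physical pairing, and the π–π
  classifier folds to `min(θ, 180° − θ)` before applying its boundaries
  (≤ 30° parallel-like, ≥ 60° T-shaped, in between intermediate; both
  configurable — the physical anchors are 90° for a perpendicular pair and
  0/180° for a stacked one, and the 30/60 split is this package's
  convention for the qualitative labels).
- **Torsions** follow the IUPAC sign convention, verified against gemmi's
  independent implementation, reported in (−180°, 180°]. Note the torsion
  is *invariant* under reading the four atoms in reverse order and changes
  sign under mirror reflection.
- **Superposition** is the least-squares optimal proper rotation (Kabsch,
  via SciPy's `Rotation.align_vectors` after centering; determinant +1
  guaranteed). For inter-structure groove comparisons the fitting frame is
  the heavy-chain Cα set of author numbers 1–180 **intersected with
  residues resolved in both structures** — with disordered stretches in one
  partner, any comparison is only well-defined on the mutual set. Per-atom
  shifts are Euclidean distances between the reference atom and the
  transformed mobile atom.

## Interaction descriptors

The P1 probe is chosen by residue identity: aromatic P1 → ring centroid,
alanine (or other non-aromatic) P1 → Cβ. This one dispatch rule encodes the
dual distance definitions used for Phe- versus Ala-bearing peptides.

- **CH–π** (Ile52 → P1 ring): contact iff ring-centroid-to-Cδ distance
  ≤ 5.5 Å *and* C–H–centroid angle ≥ 120°. The thresholds bracket the
  ~5 Å distance peaks and 120–150° angle range characteristic of stable
  CH–π contacts in these complexes; they are package conventions, exposed
  as configuration. Crystal structures carry no hydrogens, so the Cδ
  hydrogen is constructed when absent: 1.09 Å from Cδ at tetrahedral
  geometry, choosing among the three staggered positions about the
  Cγ1–Cδ axis the one most linear toward the query ring. An explicit
  hydrogen within 1.2 Å of Cδ (MD frames) always wins and is flagged.
- **Hydrogen bonds** are heavy-atom only: N/O pairs across residues at
  ≤ 3.5 Å, excluding the covalently related backbone O(i)···N(i+1) pair
  across the peptide bond (the only 1-2/1-3 N/O pair spanning residues).
  No donor-geometry angle is invented for structures without hydrogens;
  angle-refined detection would only be meaningful on MD frames.
- **Hydrophobic contacts** are side-chain C···C pairs ≤ 4.5 Å,
  deduplicated to one contact per residue pair at the minimum distance.

## Trajectory statistics

- **RMSF**: each frame is Kabsch-fit to a reference over an alignment
  selection (default: all Cα of the analysed chain); the reference is
  iterated to the time-average structure (two passes). A residue's RMSF is
  the root-mean-square displacement of its chosen atom (default Cα) from
  its time-average position. For isotropic per-coordinate Gaussian noise of
  width σ the expectation is √3·σ — the closed form used for validation.
- **ω trace**: the torsion Cys76:CA–P7:CA–P1:CA–P1:N per frame. Unwrapping
  requires each neighbouring-frame step to be < 180° in magnitude,
  shifting values by the unique multiple of 360° otherwise; a step of
  exactly 180° resolves toward the positive shift. Shift counts are
  accumulated as integers so the output is exactly congruent to the input
  modulo 360°. Smoothing is a centered moving average over all samples
  within ± window/2 (default window 10 ns); edges use the truncated
  window so the trace keeps its length (a linear ramp is a fixed point in
  the interior). A window shorter than one frame interval returns the
  input with a warning.
- **Canonical-rotation detection**: the smoothed trace reduced modulo 360°
  into (−180°, 180°] must stay within `canonical ± tolerance` continuously
  for at least the dwell time. Defaults: 97° ± 45°, dwell 50 ns — centred
  between the canonical "down" values of the short-peptide structures
  (96°, 98°) and their 100° periodic equivalents, wide enough to absorb
  thermal scatter yet excluding the "up" orientations near −70° to −110°;
  the dwell requirement rejects transient crossings. All configurable.
- **Distributions**: fixed-width histograms (defaults 0.2 Å for distances,
  5° for angles), normalised to unit probability; the peak is the center of
  the modal bin with ties to the lowest value; the width metric is the
  empirical IQR of the raw samples. An equilibration stretch can be
  discarded (`discard_initial`, default 0 ps — the package analyses the
  ensemble it is given, with equal frame weights).

## The synthetic generator

`make_scaffold` builds a geometric idealisation, not a physical conformer:
heavy-chain Cα on a regular helical path (3.8 Å between neighbours),
backbone N/C/O placed by two-sphere closure so every within- and
between-residue bond is 1.2–1.6 Å, planar regular aromatic rings, and the
conserved groove residues (Tyr7, Ile52, Tyr59, Arg62, Asn63, Cys76, Tyr159,
Trp167, Tyr171) at their author numbers with Ile52/Tyr59 side chains
reaching toward a shared pocket. The peptide P1 side chain is planted by
inverse construction: the ring centroid is placed to satisfy the requested
Cδ distance and C–H–centroid angle exactly (root-finding on the closed-form
angle equation), the azimuth is chosen to match the requested Tyr59
distance where the constraint circle allows (the achieved value is what the
ledger records), and the ring normal is set at the requested angle to the
Tyr59 normal. Gaps are removed only after planting — mirroring an analysis
whose disordered residues existed in the modelling template. ω can be
planted by rotating the P1 amide nitrogen about the P7:CA–P1:CA axis with a
one-degree probe rotation calibrating the handedness.

`make_trajectory` realises ω schedules (constant, linear ramp, piecewise)
and descriptor distance schedules exactly before adding isotropic per-atom
Gaussian noise with per-residue widths; one seed drives named random
streams, so outputs are byte-identical under a fixed seed. Every generator
returns a JSON-serialisable ledger of the planted ground truth, and the
test suite checks each analysis operation against the ledger, never against
the request when the two can differ.

What the fixtures do **not** emulate: force-field energetics, solvent,
replica-exchange statistics, correlated backbone motion, anisotropic B
factors, or realistic side-chain rotamers. Passing tests therefore
establish the correctness of the geometric and statistical computations,
not the physical realism of any ensemble; analyses of real trajectories
inherit whatever sampling quality the input has.

## Problem sizes and validation choices

The validation suite runs at desk scale: 180-residue scaffolds; 2,000
frames for the RMSF closed-form check (±5%); 50,000 draws for
distribution-peak recovery (within one bin); 1,000 random wrapped walks
against a brute-force unwrapping oracle; 200 random gap patterns against a
set-difference oracle; ω-schedule recovery asserted to 0.01° at zero noise
(file round-trips add ~0.04° from the 0.001-Å PDB coordinate precision).
Microsecond-scale ensembles and 30-replica exchange sampling are outside
desk scale; the identical computations are exercised on ledgered synthetic
ensembles instead. Checks against the deposited crystal entries (ω values,
gap counts, groove r.m.s.d., P1/P2 Cα shifts) require fetching the four PDB
entries and run only where those files are available.

## Known limitations

- Hydrogen-bond detection has no angular term on hydrogen-free input; weak
  or bifurcated bonds are not distinguished.
- The CH–π criterion is a geometric convention; no energetic scoring.
- `mmCIF` is read-only; writing is fixed-width PDB (coordinates outside
  the field range raise a serialization error rather than being clamped).
- The superposition atom set for inter-structure shifts (mutually resolved
  groove Cα) is a convention; shifts of a few Å are robust to it, shifts
  near its own r.m.s.d. are not.
- REMD ensembles are treated as equally weighted frames; no reweighting.
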