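# mhcgroove

Geometric and statistical analysis of MHC class I peptide-binding grooves —
crystal structures and conformational ensembles.

MHC class I (MHC I) molecules present short peptides to CD8+ T cells in a
groove lined by pockets A–F. During peptide loading the N-terminus of the
groove (pocket A, the 3₁₀-helix around Ile52, and the conserved Tyr59) can
distort substantially: long peptides with bulky position-1 (P1) side chains
leave stretches of heavy-chain residues crystallographically disordered and
trap the peptide's N-terminal amino group in a rotated, non-canonical
orientation. `mhcgroove` implements the measurements needed to characterise
these intermediates:

- **Disorder detection** — missing-residue (gap) reports for a chain
  against an expected author-number range, e.g. the 6-residue
  (Gln54–Tyr59) and 18-residue (Ser42–Tyr59) disordered stretches seen in
  long-peptide complexes.
- **Interaction descriptors** — the bespoke probes between peptide P1 and
  heavy-chain residues: ring-centroid distances (Cβ for alanine P1),
  ring-plane orientation angles with π–π classification (T-shaped /
  intermediate / parallel-like), and CH–π detection between the Ile52
  Cδ–H donor and the P1 aromatic ring (centroid distance ≤ 5.5 Å and
  C–H–centroid angle ≥ 120° by default; the hydrogen is taken explicitly
  when present, otherwise constructed as an idealised methyl H).
- **Contact networks** — heavy-atom hydrogen bonds (N/O pairs ≤ 3.5 Å,
  optionally including waters) and side-chain hydrophobic contacts
  (C···C ≤ 4.5 Å) over the pocket A/B region.
- **Superposition** — Kabsch fitting on mutually resolved groove Cα atoms,
  with r.m.s.d. and per-probe Cα-shift reporting (e.g. the P1 shift
  between two bound peptides).
- **Trajectory statistics** — per-residue RMSF after iterative rigid
  alignment; per-frame descriptor series and their binned probability
  distributions with modal peak and IQR; and the ω dihedral
  (Cys76:CA–P7:CA–P1:CA–P1:N) that tracks rotation of the peptide
  N-terminal amino group in pocket A, with unwrapping (neighbouring-frame
  steps forced below 180° by ±360° shifts), 10-ns sliding-window
  smoothing, and canonical-rotation ("amino group points down", ω ≈ 97°
  modulo 360°) dwell detection.
- **Synthetic ground truth** — a generator for idealised groove/peptide
  scaffolds and trajectories with planted gaps, contact geometries, ω
  schedules and seeded noise, each accompanied by a JSON ledger of the
  planted values, so every analysis stage is testable without downloads.

Structures are read and written through [gemmi](https://gemmi.readthedocs.io)
(PDB and mmCIF; multi-model PDB for ensembles) and addressed purely by
author numbering; peptide positions are symbolic (`P-2` … `P8`) through a
`PeptideMap`.

## Worked example

Generate a synthetic complex whose ω starts at −100° (amino group "up")
and ramps to 460° — equivalent to 100°, i.e. the canonical "down"
orientation — then analyse the trajectory:

```bash
mhcgroove simulate --out-dir fixtures --seed 1 --omega -100 \
    --omega-end 460 --n-frames 200 --frame-interval 20
mhcgroove analyze-trajectory fixtures/trajectory_1.pdb \
    --frame-interval 20 --p1-number 3 --window 0.2 --dwell 0.2 \
    --out-dir analysis
```

prints

```
simulate: scaffold + 1 trajectorie(s) in fixtures
analyze-trajectory: 200 frames; rotation reached=True; reports in analysis
```

and `analysis/report.json` contains (abridged):

```
"distribution_peaks": {"P1..Y59": 5.9, "P1..I52": 5.1},
"canonical_rotation": {"reached": true, "first_time_ps": 1100.0},
"omega_start": -100.04,
"omega_end_unwrapped": 460.04
```

Reading: the P1–Tyr59 and P1–Ile52 distance distributions peak at the
planted pocket geometry (≈ 5.9 Å and ≈ 5.1 Å after 0.001-Å PDB coordinate
quantisation); the unwrapped ω trace spans the full 560° of the schedule
instead of wrapping at ±180°; and the smoothed trace first dwells inside
the canonical band (97° ± 45°, reduced modulo 360°) at 1.1 ns — the point
where the ramp crosses 52°. The `omega_trace.tsv` report carries the raw,
unwrapped and smoothed series per frame time.

The same commands accept deposited crystal structures, e.g.
`mhcgroove analyze-structure entry.pdb --p1-number 13` for a 20mer complex
(P1 is author residue 13 of the peptide chain) produces the gap report,
descriptor values, π–π/CH–π classification and pocket contact networks;
`mhcgroove compare-structures` superposes two entries on their mutually
resolved groove Cα atoms and reports per-position peptide Cα shifts.

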