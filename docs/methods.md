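# Methods

This note records what the package actually computes, the modelling
choices behind it, and what those choices do and do not support.

## The reduced-atom triple helix

Each residue carries four backbone atoms (N, CA, C, O) and, for
non-glycines, a single sidechain pseudo-atom placed radially outward from
the helix axis.  Chains wind with an axial rise of 2.86 Å per residue and
a twist of −102.857° (7/2 symmetry); the three chains sit 120° apart with
a one-residue stagger.  The Cα track radius is 1.5 Å, with glycine Cα
drawn to half that radius so the glycine of every G-X-X′ triplet points
to the helix centre — the structural fact behind the "zero every third
residue" pattern in accessibility profiles.  Sidechain pseudo-atom radii
come from a per-residue table (2.1–2.9 Å) approximating sidechain girth.

This is a *geometric* stand-in, not a rotamer-accurate model.  At the
1.5 Å track radius the three chains interleave so tightly that some
backbone atoms of different chains overlap sterically; downstream
statistics (selections, RMSD/RMSF, probe accessibility, bond counting)
are insensitive to this, but per-atom energetics or packing analysis
inside one helix would not be meaningful.  Hydroxyproline is encoded as
`O` with proline-like geometry and a polar (donor/acceptor) sidechain.

Telopeptides are non-helical terminal extensions.  The N-telopeptide
continues the helix; in `folded_back` mode the C-telopeptide doubles back
along −c, lifted ~6 Å along the outward surface normal and drifting
laterally so that, once the lattice is assembled, it overlies the
neighbouring D4 segment — the geometry that occludes the GQRGER motif in
the starting structure.

## Lattice

The monomer (two α1 + one α2 chains, ~300 nm) is cut into five D-segments
by Cα axial coordinate: D1–D4 one D-period each, D5 the remaining 0.46 D
plus the C-telopeptide.  A segment of k residues at rise h is reported as
spanning k·h (Cα extent plus one rise).  The helical length per preset is
chosen so that even the stagger-2 chain's last helical residue stays
inside the overlap window; the gap region therefore contains no D5, and
the overlap contains all five segments, by construction.

Segments are packed at stylized quasihexagonal (a, b) offsets in the unit
cell — D4/D5 in the high-a row (exposed on surface A), D1 innermost
(exposed on surface B from below) — then replicated 3×3 into the 3a3b
slab.  Two presets ship: `schematic` (D = 670 Å) and `3hr2` (cell
678 × 27 × 40 Å); a `reduced` preset keeps the identical cross-section
with a 114.4 Å repeat for fast trajectory work.  Because occlusion is a
cross-section property, the reduced model reproduces the full model's
accessibility behaviour.

Axial coordinates are quantized to 0.001 Å (PDB precision) at assembly so
region labels survive file round trips.  The b-edges of the slab and the
two axial cell ends are open; accessibility profiles show small
end-effects within ~1.5 nm of the axial boundaries, which the analyses
treat as interior-exclusion artifacts.

## Synthetic dynamics

`generate_trajectory` realizes a `ModeSchedule` as explicit coordinates;
it integrates nothing and makes no claim of mechanistic realism — it
reproduces the observed geometry changes of fibril surface
reconstruction so the analysis stages can be exercised and validated
end to end.

Three deterministic modes act on the surface-A layer only:

1. **C-telopeptide shift** — 20 Å along −c (toward the N-terminus).
2. **D5 drop** — a sine-shaped lateral displacement along −b with a
   transient outward a-bulge that returns to zero by the final frame.
3. **Gap contraction** — inward (−a) displacement of surface-layer
   gap-region atoms, depth-weighted so rows closer to the surface move
   more, with a transient "breathing" oscillation (35% of the amplitude)
   that vanishes at the first and final frames.

The thermal background applies to every layer and has two parts: a small
fast per-atom jitter (σ = 0.08 Å) and a *collective drift* — a spatially
smooth random direction field (correlation length 150 Å) with a
deterministic magnitude envelope, ramped in time.  Because the magnitude
is deterministic, layer-resolved RMSD values concentrate tightly across
seeds while the direction of motion stays random.  Three residues at each
D-segment terminus (telopeptides exempt) are pinned by a restraint
envelope (×0.05), mirroring the termini restraints a fibril-periodic
simulation would impose.  The drift is locally suppressed where the D5
modes dominate, so the calibrated D5 displacement is not double-counted.

### Calibration of the calibrated preset

`calibrated_schedule` encodes the printed outcomes by construction:

- the drift amplitude is solved so the final-frame core-layer D5 Cα RMSD
  equals 4.0 Å;
- the D5 drop amplitude is solved (bisection on the analytic expectation)
  so the surface-A D5 RMSD equals 12.0 Å;
- the classified H-bond deltas are closed on *realized* counts.  The
  modes and thermal background toggle hundreds of borderline
  donor–acceptor pairs per run, so fixed scheduled counts would not
  reproduce the net deltas.  Instead a dry boundary evaluation (exactly
  replaying the seeded noise streams) measures that churn; an explicit
  inter-helix contact schedule — donor/mover pairs with engineered
  bond geometry, movers drawn from atoms unbonded at both ends of the dry
  run — is sized to the residual by fixed-point iteration; and a final
  *packing strain* (radial tightening of the surface layers' helices,
  solved by bisection on the realized final-frame count) closes the net
  protein–protein delta to +0.169 per residue.  Water expulsion is sized
  the same way from measured per-water bonds, closing the protein–water
  delta to −0.142 per residue.  Scheduled contacts form in both surface
  layers (both outer faces pack); the three conformational modes remain
  surface-A-only and the core layer receives the thermal background
  alone, verified by an exact layer-locality test.
- Rarely a thermal realization breaks more borderline bonds than the
  lattice can re-form; such realizations are rejected and the next one
  derived from the seed is calibrated instead, deterministically.

Waters are explicit pseudo-atoms anchored to surface-layer oxygens; they
ride their anchor until their scheduled expulsion frame removes them from
the surface.  Contact movers track their donor, so scheduled bonds hold
exactly from their engagement frame onward.

### What passing these checks shows — and what it does not

The trajectory targets demonstrate that the *analysis stages* (selection
logic, RMSD/RMSF, classified bond tallies, accessibility) correctly
recover displacements and bond-count changes that are present in the
coordinates.  They say nothing about force-field realism: amplitudes are
calibrated inputs, not predictions.  Two known gaps relative to real
surface reconstruction: (i) the lattice is b-commensurate, so a uniform
D5 drop cannot vacate a local cavity the way an incommensurate surface
can — the unveiling of GQRGER during the trajectory is reproduced in
sign (≈ 0 Å² rising to small positive values after the telopeptide
shift) but not in magnitude; (ii) the absolute baseline bond counts of
the pseudo-atom lattice are not comparable to all-atom counts — only the
per-residue *deltas* are calibrated quantities.

## Accessibility (SASA)

Shrake–Rupley sphere sampling with a deterministic Fibonacci point set
(960 points by default; doubling changes per-residue values by < 2%).
Probe radii: 1.4 Å (water) and 8.0 Å, the "large probe" that measures
accessibility to protein-sized partners; with it, interior surface
vanishes from the profile without any masking step, which is the entire
point of the statistic.  Per-residue values sum member atoms, then the
two α1 and the α2 chain are averaged at the same sequence position
(the stagger is a placement artifact; pairing by sequence index keeps
glycine positions averaging glycines).  In the assembled starting model
the GQRGER site scores 0 Å² at the 8.0 Å probe — buried under the
folded-back C-telopeptide and the D5 row — while D4 in the gap region
and D5 in the overlap average well above the 15 Å² display threshold.

An independent volumetric-grid oracle (0.2 Å resolution, per-voxel
coverage counting) and biotite's SASA with matched radii pin the
implementation to within 3%.

## AFM profile analysis

Profiles are detrended (order-1 least squares), the D-period is the first
dominant autocorrelation peak with parabolic sub-sample refinement, and
the step height is the per-period max-minus-min on a Gaussian-smoothed
profile (σ = period/20) in phase-aligned windows, reported as mean ± sd
over complete periods.  The synthetic generator emits a smoothed
two-level waveform (high plateau fraction 0.46 = the overlap), 67 nm
period, 4.1 nm amplitude, 2 nm edge width, 0.3 nm Gaussian noise and a
2 nm/µm tilt at 1 nm sampling.  Noise maxima bias the peak-minus-valley
estimator upward by ~3% at these settings (4.25 vs 4.10 nm over 50
seeds), within the ±0.4 nm experimental spread the statistic is compared
against.  White-noise inputs raise a "no dominant period" error rather
than returning a number.

## Numerical conventions

- Lengths in Å internally; nm in reports; angles in degrees.
- H-bond criterion: donor–acceptor ≤ 3.0 Å and antecedent–donor–acceptor
  angle ≥ 120° (the reduced model has no hydrogens, so the angle is taken
  at the donor's Cα; waters have no antecedent and pass the angle test).
  Covalent neighbours (same residue; adjacent-residue backbone pairs) are
  excluded; unordered pairs are counted once.
- RMSD uses Cα only, mass-unweighted, no superposition by default
  (restrained termini give displacement meaning in the fixed frame);
  Kabsch superposition is available as `fit="rigid"`.
- RMSF discards the first 40% of frames as equilibration.
- Same seed ⇒ bit-identical trajectories and profiles; SASA contains no
  randomness at all.
- Problem sizes: trajectory analyses run on the `reduced` preset
  (114.4 Å repeat, ~24.5k atoms, 101 frames); lattice geometry and
  accessibility checks run on the full `schematic`/`3hr2` models
  (~137k atoms), where the accessibility targets are computed only for
  the motif residues while every atom occludes.
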