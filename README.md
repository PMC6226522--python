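# fibrilsurf

Type I collagen fibrils bury most of their receptor-binding motifs inside a
quasihexagonally packed lattice of triple helices.  How do integrins,
MMPs and other partners ever reach them?  One answer is *surface
reconstruction*: the outermost monomers of the fibril are not static --
the C-telopeptide translates toward the N-terminus, the D5 segment drops
out of its lattice position, and the surface layer of the gap region
contracts and sheds bound water -- transiently exposing cryptic sites such
as the integrin αI-domain motif GQRGER.

`fibrilsurf` is a reusable pipeline for studying this picture at desk
scale.  It builds the D-periodic fibril-surface lattice from chain
sequences, generates synthetic surface-reconstruction trajectories that
realize the three conformational modes, and quantifies the reconstruction
with the analyses used in the field:

- **Lattice construction** — an idealized triple-helix builder
  (rise 2.86 Å, 7/2 twist; reduced N/CA/C/O + sidechain pseudo-atom
  model), decomposition of the ~300 nm monomer into five D-segments
  (D1–D4 of length *D* = 67 nm, D5 = 0.46 *D*), packing into the smallest
  repeating unit (SRU; unit cell 678 × 27 × 40 Å in the calibrated
  preset), and 3×3 replication into the two-surface "3a3b" slab
  (surface A exposes D4/D5; surface B exposes D1; a core layer between).
- **Trajectory metrics** — layer- and segment-resolved Cα RMSD
  (no superposition by default; the termini are restrained in a fixed
  frame) and per-residue RMSF over an equilibrated window.
- **Hydrogen-bond tallies** — geometric detection (3.0 Å heavy-atom
  distance, 120° donor-antecedent angle) classified protein–protein vs
  protein–water, intra- vs inter-triple-helix, backbone–backbone vs
  sidechain-involved, normalized per residue.
- **Large-probe accessibility** — Shrake–Rupley SASA with a configurable
  probe; the 8.0 Å probe measures accessibility to protein-sized binders
  and makes fibril-interior surface vanish from the profile.  Per-residue
  values are chain-averaged across the heterotrimer (two α1 + one α2).
- **Motif mapping** — scans for the minimal integrin motif G-X-X′-G-E-X″
  and named sites (GQRGER), located on segment / axial position / region.
- **AFM banding analysis** — D-period estimation by autocorrelation and
  overlap–gap step-height statistics from 1-D height profiles, with a
  matching synthetic D-banded profile generator.

The synthetic-dynamics generator is calibrated so that its trajectories
reproduce, by construction, the hallmark numbers of the reconstruction:
final D5 RMSD ≈ 12 Å in the surface layer vs ≈ 4 Å in the core, a net gain
of +0.169 protein–protein H-bonds per residue with −0.142 protein–water
H-bonds per residue, a 67 nm D-banding periodicity and a 4.1 nm
overlap–gap step height.

The bundled α1/α2 chains are clearly-labelled *synthetic stand-ins* with
collagen architecture ((G-X-X′)ₙ triplets, telopeptides, GQRGER on D4 at
the overlap edge), not the natural sequences.

## Worked example

```python
from fibrilsurf import (build_model, calibrated_schedule, generate_trajectory,
                        rmsd_series, tally_series)

model = build_model("reduced")          # compact 3a3b lattice
sched = calibrated_schedule(model, seed=42)  # calibrated mode schedule
traj = generate_trajectory(model, sched)

surf = rmsd_series(traj, {"segment": "D5", "layer": "surface_A",
                          "representative": True})
core = rmsd_series(traj, {"segment": "D5", "layer": "core",
                          "representative": True})
tally = tally_series(traj)
print(f"final D5 RMSD: surface {surf.final:.1f} A, core {core.final:.1f} A")
print(f"H-bond deltas per residue: "
      f"protein-protein {tally.delta_pp_per_residue:+.3f}, "
      f"protein-water {tally.delta_pw_per_residue:+.3f}")
```

prints

```
final D5 RMSD: surface 12.1 A, core 4.0 A
H-bond deltas per residue: protein-protein +0.169, protein-water -0.142
```

The D5 segment on the interaction surface ends the run displaced three
times as far as the same segment in the fibril core, while the packing
tightens: about one new protein–protein hydrogen bond forms for every six
residues, paid for by expelled surface water.  The same pipeline is
scriptable from the shell:

```
fibrilsurf build --preset schematic --out model.pdb
fibrilsurf afm --synthetic --seed 42
# {"period_nm": 66.93, "step_height_mean_nm": 4.22, ...}
fibrilsurf motifs --pattern GQRGER
```

## Layout

- `src/fibrilsurf/` — the library: `builder` (triple helix), `lattice`
  (D-segments / SRU / 3a3b), `sequences` (synthetic chains), `dynamics`
  (mode schedules, trajectories, AFM profile generator), `metrics`
  (RMSD/RMSF), `hbonds`, `sasa`, `motifs`, `afm`, `io`, `cli`.
- `docs/methods.md` — the model, its assumptions, parameter choices and
  known limitations.
- `tests/` — unit, property and end-to-end suites with brute-force
  oracles.
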