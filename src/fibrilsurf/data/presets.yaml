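# Lattice presets.  Lengths in Angstrom, angles in degrees.
#
# schematic : D-period 670 A (67 nm), the canonical banding length.
# 3hr2      : fibre-diffraction calibrated unit cell, 678 x 27 x 40 A.
# reduced   : same cross-section, 40 residues per D-period; compact substrate
#             for the synthetic trajectory analyses.
#
# segment_offsets place the five D-segment helix axes quasihexagonally in the
# (a, b) cross-section: D4/D5 in the high-a row so that surface A exposes
# them, D1 innermost (surface B exposes it from below).

schematic:
  d_period: 670.0
  d5_fraction: 0.46
  cell_a: 40.0
  cell_b: 27.0
  cell_c: 670.0
  axial_rise: 2.86
  twist: -102.85714285714286
  helix_radius: 1.5
  sidechain_offset: 3.0
  glycine_radius_scale: 0.5
  helical_residues: 1043
  n_telo: 16
  c_telo: 25
  fold_lift: 6.0
  fold_drift_b: -13.5
  segment_offsets:
    D1: [7.0, 13.5]
    D2: [14.0, 0.0]
    D3: [21.0, 13.5]
    D4: [28.5, 0.0]
    D5: [35.0, 13.5]

3hr2:
  d_period: 678.0
  d5_fraction: 0.46
  cell_a: 40.0
  cell_b: 27.0
  cell_c: 678.0
  axial_rise: 2.8941492537313433
  twist: -102.85714285714286
  helix_radius: 1.5
  sidechain_offset: 3.0
  glycine_radius_scale: 0.5
  helical_residues: 1043
  n_telo: 16
  c_telo: 25
  fold_lift: 6.0
  fold_drift_b: -13.5
  segment_offsets:
    D1: [7.0, 13.5]
    D2: [14.0, 0.0]
    D3: [21.0, 13.5]
    D4: [28.5, 0.0]
    D5: [35.0, 13.5]

reduced:
  d_period: 114.4
  d5_fraction: 0.46
  cell_a: 40.0
  cell_b: 27.0
  cell_c: 114.4
  axial_rise: 2.86
  twist: -102.85714285714286
  helix_radius: 1.5
  sidechain_offset: 3.0
  glycine_radius_scale: 0.5
  helical_residues: 177
  n_telo: 8
  c_telo: 8
  fold_lift: 6.0
  fold_drift_b: -13.5
  segment_offsets:
    D1: [7.0, 13.5]
    D2: [14.0, 0.0]
    D3: [21.0, 13.5]
    D4: [28.5, 0.0]
    D5: [35.0, 13.5]
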