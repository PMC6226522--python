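"""D-segment decomposition and the SRU / 3a3b fibril surface lattice.

The monomer triple helix is cut into five D-segments (D1-D4 one D-period
each, D5 the remaining 0.46 D plus the C-telopeptide), which are packed at
quasihexagonal (a, b) offsets into a single unit cell one D-period long: the
smallest repeating unit (SRU) of the fibril, containing the complete chain
sequence distributed over five staggered segments.  Replicating the SRU
3 x 3 along depth (a) and width (b) gives the "3a3b" slab whose outer faces
are the two candidate fibril surfaces: surface A (D4/D5 exposed, the
interaction surface studied here) at high a and surface B (D1 exposed) at
low a, sandwiching a core layer.

Axial origin convention: the N-terminal end of D1 sits at axial 0; the
overlap region (all five segments present) is [0, 0.46 c) and the gap region
(D5 absent) is the remainder of the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .builder import TripleHelix, build_triple_helix, place_telopeptides
from .config import FibrilGeometry, Preset, UnitCell, get_preset
from .sequences import chains_for_preset

SEGMENTS = ("D1", "D2", "D3", "D4", "D5")
LAYER_BY_COPY_A = {0: "surface_B", 1: "core", 2: "surface_A"}

CLASH_DISTANCE = 1.5  # A, warn below this inter-segment atom distance


@dataclass
class DSegment:
    """One D-period-length fragment of the monomer."""

    segment: str
    atoms: pd.DataFrame
    rise: float = 2.86

    @property
    def residue_count(self) -> int:
        return int((self.atoms["name"] == "CA").sum())

    def axial_extent(self, include_telopeptide: bool = False) -> float:
        """Calpha axial span (max - min); telopeptides are non-helical
        appendages and are excluded by default, so the extent is a
        helical-domain property."""
        sel = self.atoms["name"] == "CA"
        if not include_telopeptide:
            sel &= ~self.atoms["is_telopeptide"]
        z = self.atoms.loc[sel, "z"].to_numpy()
        return float(z.max() - z.min())

    def axial_length(self) -> float:
        """Axial span covered by the segment's residues: a run of k residues
        at rise h occupies k*h, i.e. the Calpha extent plus one rise."""
        return self.axial_extent() + self.rise


@dataclass
class FibrilModel:
    """Atoms plus lattice labels; the container every analysis consumes."""

    atoms: pd.DataFrame
    cell: UnitCell
    geometry: FibrilGeometry
    preset_name: str | None = None

    @property
    def n_copies(self) -> int:
        return len(self.atoms.groupby(["copy_a", "copy_b"]).groups)

    @property
    def n_residues(self) -> int:
        """Protein residue count (one CA per residue)."""
        prot = self.atoms["role"] != "water"
        return int(((self.atoms["name"] == "CA") & prot).sum())

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def representative_copy_b(self) -> int:
        return int(np.median(self.atoms["copy_b"].unique()))

    def mask(
        self,
        segment: str | tuple[str, ...] | None = None,
        layer: str | None = None,
        region: str | None = None,
        name: str | None = None,
        chain: str | None = None,
        representative: bool = False,
        protein_only: bool = True,
        exclude_telopeptide: bool = False,
    ) -> np.ndarray:
        """Boolean atom selection over the label columns."""
        a = self.atoms
        m = np.ones(len(a), dtype=bool)
        if protein_only:
            m &= (a["role"] != "water").to_numpy()
        if segment is not None:
            segs = (segment,) if isinstance(segment, str) else tuple(segment)
            m &= a["segment"].isin(segs).to_numpy()
        if layer is not None:
            m &= (a["layer"] == layer).to_numpy()
        if region is not None:
            m &= (a["region"] == region).to_numpy()
        if name is not None:
            m &= (a["name"] == name).to_numpy()
        if chain is not None:
            m &= (a["chain"] == chain).to_numpy()
        if representative:
            m &= (a["copy_b"] == self.representative_copy_b).to_numpy()
        if exclude_telopeptide:
            m &= (~a["is_telopeptide"]).to_numpy()
        return m


def monomer_for_preset(
    preset: Preset | str,
    telo_mode: str = "folded_back",
    chains: tuple[str, str, str] | None = None,
) -> TripleHelix:
    """Build the heterotrimer monomer configured by a lattice preset."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if chains is None:
        chains = chains_for_preset(preset)
    helix = build_triple_helix(*chains, params=preset.helix)
    return place_telopeptides(
        helix, preset.n_telo, preset.c_telo, mode=telo_mode,
        fold_lift=preset.fold_lift, fold_drift_b=preset.fold_drift_b,
    )


def segment_monomer(
    monomer: TripleHelix, geom: FibrilGeometry, tolerance: float = 0.03
) -> list[DSegment]:
    """Cut the monomer into D1..D5 by Calpha axial coordinate.

    The helical domain must span (4 + d5_fraction) D-periods to within
    ``tolerance``; residues are assigned to the segment whose axial window
    contains their Calpha (telopeptides clip to D1/D5).
    """
    d = geom.d_period
    hz = monomer.helical_calpha()["z"].to_numpy()
    length = float(hz.max() - hz.min())
    expected = (4.0 + geom.d5_fraction) * d
    if abs(length - expected) > tolerance * expected:
        raise ValueError(
            f"monomer helical length {length:.1f} A incompatible with "
            f"(4 + {geom.d5_fraction}) x {d:.0f} = {expected:.1f} A"
        )
    atoms = monomer.atoms
    ca = atoms[atoms["name"] == "CA"]
    seg_idx = np.clip((ca["z"].to_numpy() // d).astype(int), 0, 4)
    res_seg = {
        (c, r): SEGMENTS[s]
        for c, r, s in zip(ca["chain"], ca["res_index"], seg_idx)
    }
    seg_col = [res_seg[(c, r)] for c, r in zip(atoms["chain"], atoms["res_index"])]
    out = []
    for name in SEGMENTS:
        sel = atoms[np.array(seg_col) == name].copy()
        sel["segment"] = name
        out.append(DSegment(segment=name, atoms=sel.reset_index(drop=True),
                            rise=monomer.params.axial_rise))
    total = sum(s.residue_count for s in out)
    n_res = int((atoms["name"] == "CA").sum())
    assert total == n_res, "segment residue counts must sum to the monomer"
    return out


def assemble_sru(
    segments: list[DSegment],
    cell: UnitCell,
    geometry: FibrilGeometry,
    segment_offsets: dict[str, tuple[float, float]],
    preset_name: str | None = None,
) -> FibrilModel:
    """Pack the five D-segments into one unit cell (the SRU).

    Each segment is translated to its quasihexagonal (a, b) offset and its
    axial coordinate is rebased into [0, c) (segment k loses k D-periods;
    telopeptides wrap modulo c).  Emits a warning when any inter-segment
    atom pair comes closer than the clash threshold.
    """
    d = geometry.d_period
    frames = []
    for k, seg in enumerate(segments):
        if seg.segment not in segment_offsets:
            raise KeyError(f"no (a,b) offset for segment {seg.segment}")
        a_off, b_off = segment_offsets[seg.segment]
        df = seg.atoms.copy()
        df["x"] = df["x"] + a_off
        df["y"] = df["y"] + b_off
        # quantize to PDB precision so the in-cell coordinate (and the
        # region it implies) survives a write/read round trip
        df["z"] = np.round(np.mod(df["z"] - k * d, cell.c), 3)
        frames.append(df)
    atoms = pd.concat(frames, ignore_index=True)
    # region from the residue's Calpha axial position
    ca = atoms[atoms["name"] == "CA"]
    junction = geometry.d5_fraction * cell.c
    res_region = {
        (s, c, r): ("overlap" if z < junction else "gap")
        for s, c, r, z in zip(ca["segment"], ca["chain"], ca["res_index"], ca["z"])
    }
    atoms["region"] = [
        res_region[(s, c, r)]
        for s, c, r in zip(atoms["segment"], atoms["chain"], atoms["res_index"])
    ]
    atoms["copy_a"] = 0
    atoms["copy_b"] = 0
    atoms["layer"] = ""
    _warn_on_clashes(atoms)
    return FibrilModel(atoms=atoms, cell=cell, geometry=geometry,
                       preset_name=preset_name)


def _warn_on_clashes(atoms: pd.DataFrame) -> None:
    xyz = atoms[["x", "y", "z"]].to_numpy(float)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(CLASH_DISTANCE, output_type="ndarray")
    if len(pairs):
        seg = atoms["segment"].to_numpy()
        inter = pairs[seg[pairs[:, 0]] != seg[pairs[:, 1]]]
        if len(inter):
            dists = np.linalg.norm(xyz[inter[:, 0]] - xyz[inter[:, 1]], axis=1)
            warnings.warn(
                f"{len(inter)} inter-segment atom pairs closer than "
                f"{CLASH_DISTANCE} A (worst {dists.min():.2f} A)",
                stacklevel=3,
            )


def replicate_lattice(sru: FibrilModel, na: int = 3, nb: int = 3) -> FibrilModel:
    """Replicate the SRU na x nb along depth (a) and width (b).

    Layer labels follow the depth index: the highest-a copies form surface A,
    the lowest surface B, everything between is core.  The middle-b copies
    are the representative microfibrils used for layer-resolved analyses.
    """
    frames = []
    for ia in range(na):
        for ib in range(nb):
            df = sru.atoms.copy()
            df["x"] = df["x"] + ia * sru.cell.a
            df["y"] = df["y"] + ib * sru.cell.b
            df["copy_a"] = ia
            df["copy_b"] = ib
            if ia == na - 1:
                df["layer"] = "surface_A"
            elif ia == 0:
                df["layer"] = "surface_B"
            else:
                df["layer"] = "core"
            frames.append(df)
    atoms = pd.concat(frames, ignore_index=True)
    return FibrilModel(atoms=atoms, cell=sru.cell, geometry=sru.geometry,
                       preset_name=sru.preset_name)


def build_model(
    preset: Preset | str = "schematic",
    telo_mode: str = "folded_back",
    replicate: bool = True,
    chains: tuple[str, str, str] | None = None,
) -> FibrilModel:
    """Monomer -> D-segments -> SRU -> (optionally) 3a3b in one call."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    monomer = monomer_for_preset(preset, telo_mode=telo_mode, chains=chains)
    segments = segment_monomer(monomer, preset.geometry)
    sru = assemble_sru(segments, preset.cell, preset.geometry,
                       preset.segment_offsets, preset_name=preset.name)
    return replicate_lattice(sru) if replicate else sru
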