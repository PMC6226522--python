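"""File formats: FASTA sequences, labelled PDB models, trajectories, CSV.

PDB layout: standard ATOM records with a CRYST1 card carrying the unit
cell.  Lattice labels ride in standard columns -- chain ID (A/B/C, or W
for water pseudo-atoms), the segment identifier field (columns 73-76)
encodes ``<copy_a><copy_b><segment>`` (e.g. ``21D4``), and the B-factor
column flags telopeptide residues (1.00) vs helical ones (0.00).
Round-tripping a model restores every label; coordinates keep the
format's 0.001 A precision.

Trajectories are written either as multi-model PDB or as a small flat
binary: magic ``FSRJ``, version, int32 n_atoms / n_frames / has_presence,
then float32 coordinates frame by frame, then (optionally) the per-frame
uint8 presence mask.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .builder import BACKBONE_RADII, SIDECHAIN_RADII
from .config import FibrilGeometry, UnitCell
from .lattice import FibrilModel

_MAGIC = b"FSRJ"
_VERSION = 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Chain sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "O": "HYP", "-": "HOH",
}
_AA1 = {v: k for k, v in _AA3.items()}


def _segid(copy_a: int, copy_b: int, segment: str) -> str:
    return f"{copy_a}{copy_b}{segment[:2]}"


def write_model(model: FibrilModel, path, coords: np.ndarray | None = None,
                model_number: int | None = None, file_handle=None) -> None:
    """Write a FibrilModel as a labelled PDB file."""
    own = file_handle is None
    fh = open(path, "w") if own else file_handle
    try:
        if model_number is None or model_number == 1:
            fh.write(
                f"CRYST1{model.cell.a:9.3f}{model.cell.b:9.3f}"
                f"{model.cell.c:9.3f}  90.00  90.00  90.00 P 1           1\n"
            )
        if model_number is not None:
            fh.write(f"MODEL     {model_number:4d}\n")
        atoms = model.atoms
        xyz = coords if coords is not None else model.coords()
        serial = 0
        for row, (x, y, z) in zip(atoms.itertuples(), xyz):
            serial += 1
            name = row.name if row.name != "SC" else "SC"
            resname = _AA3.get(row.aa, "UNK")
            bfac = 1.0 if row.is_telopeptide else 0.0
            seg = _segid(row.copy_a, row.copy_b, row.segment) \
                if "segment" in atoms.columns else "    "
            fh.write(
                f"ATOM  {serial % 100000:5d} {name:>4.4s} {resname:<3.3s} "
                f"{row.chain:1.1s}{row.res_index % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfac:6.2f}      "
                f"{seg:<4.4s}{row.element:>2.2s}\n"
            )
        if model_number is not None:
            fh.write("ENDMDL\n")
        else:
            fh.write("END\n")
    finally:
        if own:
            fh.close()


def read_model(path, geometry: FibrilGeometry | None = None) -> FibrilModel:
    """Read a labelled PDB written by :func:`write_model`.

    Raises a parse error naming the offending line on malformed records.
    """
    cell = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("CRYST1"):
                try:
                    cell = UnitCell(
                        a=float(line[6:15]), b=float(line[15:24]),
                        c=float(line[24:33]),
                    )
                except ValueError as exc:
                    raise ValueError(f"bad CRYST1 at line {ln}: {exc}")
            elif line.startswith(("ATOM", "HETATM")):
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21]
                    res_index = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    bfac = float(line[60:66]) if line[60:66].strip() else 0.0
                    seg = line[72:76].strip()
                    element = line[76:78].strip()
                except ValueError as exc:
                    raise ValueError(f"malformed ATOM at line {ln}: {exc}")
                aa = _AA1.get(resname, "X")
                role = ("water" if resname == "HOH"
                        else "sidechain" if name == "SC" else "backbone")
                if role == "water":
                    radius = 1.4
                elif role == "sidechain":
                    radius = SIDECHAIN_RADII.get(aa, 2.5)
                else:
                    radius = BACKBONE_RADII.get(name, 1.7)
                copy_a = int(seg[0]) if len(seg) == 4 else 0
                copy_b = int(seg[1]) if len(seg) == 4 else 0
                segment = seg[2:] if len(seg) == 4 else ""
                rows.append({
                    "chain": chain, "res_index": res_index, "aa": aa,
                    "name": name, "element": element, "role": role,
                    "radius": radius, "is_glycine": aa == "G",
                    "is_telopeptide": bfac >= 0.5,
                    "x": x, "y": y, "z": z,
                    "segment": segment,
                    "copy_a": copy_a, "copy_b": copy_b,
                })
            elif line.startswith("ENDMDL"):
                break
    if cell is None:
        raise ValueError("missing CRYST1 record")
    if not rows:
        raise ValueError("no ATOM records found")
    atoms = pd.DataFrame(rows)
    geometry = geometry or FibrilGeometry(d_period=cell.c)
    junction = geometry.d5_fraction * cell.c
    # region follows the residue's Calpha axial position; coordinates are
    # already in-cell, so no re-wrapping (a residue exactly at z = c stays
    # on the gap side, matching the builder's convention)
    ca = atoms[atoms["name"].isin(["CA", "W"])]
    key_cols = ["copy_a", "copy_b", "segment", "chain", "res_index"]
    res_region = {
        tuple(k): ("overlap" if z < junction else "gap")
        for *k, z in ca[key_cols + ["z"]].itertuples(index=False)
    }
    atoms["region"] = [
        res_region.get(tuple(k), "gap")
        for k in atoms[key_cols].itertuples(index=False)
    ]
    n_a = atoms["copy_a"].max()
    atoms["layer"] = np.select(
        [atoms["copy_a"] == n_a, atoms["copy_a"] == 0],
        ["surface_A", "surface_B"], default="core",
    )
    if n_a == 0:
        atoms["layer"] = ""
    return FibrilModel(atoms=atoms, cell=cell, geometry=geometry)


def write_trajectory_pdb(traj, path) -> None:
    """Multi-model PDB, one MODEL per frame."""
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            write_model(traj.topology, path, coords=traj.coords[t],
                        model_number=t + 1, file_handle=fh)
        fh.write("END\n")


# ---------------------------------------------------------------------------
# flat binary trajectory
# ---------------------------------------------------------------------------

def write_trajectory_binary(traj, path) -> None:
    has_presence = traj.presence is not None
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<iiii", _VERSION, traj.n_atoms,
                             traj.n_frames, int(has_presence)))
        fh.write(traj.coords.astype("<f4").tobytes())
        if has_presence:
            fh.write(traj.presence.astype(np.uint8).tobytes())


def read_trajectory_binary(path, topology: FibrilModel | None = None):
    """Read a flat binary trajectory; returns a Trajectory when a topology
    is supplied, else (coords, presence)."""
    from .dynamics import NS_PER_FRAME, Trajectory

    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"not a fibrilsurf trajectory (magic {magic!r})")
        version, n_atoms, n_frames, has_presence = struct.unpack(
            "<iiii", fh.read(16))
        if version != _VERSION:
            raise ValueError(f"unsupported trajectory version {version}")
        coords = np.frombuffer(
            fh.read(n_frames * n_atoms * 12), dtype="<f4"
        ).reshape(n_frames, n_atoms, 3).astype(float)
        presence = None
        if has_presence:
            presence = np.frombuffer(
                fh.read(n_frames * n_atoms), dtype=np.uint8
            ).reshape(n_frames, n_atoms).astype(bool)
    if topology is None:
        return coords, presence
    if len(topology.atoms) != n_atoms:
        raise ValueError("topology atom count does not match trajectory")
    return Trajectory(topology=topology, coords=coords,
                      frame_times=np.arange(n_frames) * NS_PER_FRAME,
                      presence=presence)


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def write_profile_csv(profile, path) -> None:
    """AFM height profile as 2-column CSV (position_nm, height_nm)."""
    profile.to_frame().to_csv(path, index=False)


def read_profile_csv(path):
    from .afm import HeightProfile

    df = pd.read_csv(path)
    cols = list(df.columns)
    return HeightProfile(df[cols[0]].to_numpy(float),
                         df[cols[1]].to_numpy(float),
                         {"source": str(path)})
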