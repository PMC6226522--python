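"""Solvent-accessible surface area with a configurable probe radius.

Shrake-Rupley sphere sampling: each atom is wrapped in a shell of test
points at radius r_vdw + probe; a point is exposed when it lies outside
every other atom's inflated sphere, and the atom's SASA is the exposed
fraction times the shell area.  The point set is a deterministic Fibonacci
lattice, so results carry no sampling randomness.

Two probe sizes matter here: 1.4 A (water) for conventional surface area,
and a large 8.0 A probe that measures accessibility to protein-sized
binding partners -- with the large probe the narrow interstices of the
fibril interior admit no probe centre, so interior residues score ~0 and
the profile isolates the true interaction surface.  Per-residue values sum
the member atoms and are then averaged across the three chains of each
triple helix at the aligned (stagger-removed) sequence position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import LARGE_PROBE, N_SPHERE_POINTS, SASA_HIGHLIGHT_THRESHOLD
from .lattice import FibrilModel


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ], axis=1)


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_sphere_points: int = N_SPHERE_POINTS,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (A^2); all atoms occlude, SASA computed for ``targets``
    (row indices; default all).

    Deterministic for a fixed point count.  Rejects NaN coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.isnan(coords).any():
        raise ValueError("NaN coordinates")
    if n_sphere_points < 64:
        raise ValueError("need at least 64 sphere points")
    if (radii <= 0).any():
        raise ValueError("vdW radii must be positive")
    pts = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = radii.max() + probe
    if targets is None:
        targets = np.arange(len(coords))
    out = np.zeros(len(coords))
    all_nbrs = tree.query_ball_point(coords[targets], max_reach + radii[
        targets] + probe)
    for i, nbr in zip(targets, all_nbrs):
        shell_r = radii[i] + probe
        nbr = np.array([j for j in nbr if j != i])
        if len(nbr) == 0:
            out[i] = 4.0 * np.pi * shell_r**2
            continue
        shell = coords[i] + shell_r * pts
        # nearest occluders first: most shell points die early, so walk
        # neighbours in distance order over the surviving points only
        dn = np.linalg.norm(coords[nbr] - coords[i], axis=1)
        order = np.argsort(dn)
        nbr = nbr[order]
        alive = np.arange(n_sphere_points)
        for j0 in range(0, len(nbr), 8):
            js = nbr[j0:j0 + 8]
            d2 = np.sum(
                (shell[alive][:, None, :] - coords[js][None, :, :]) ** 2,
                axis=2,
            )
            keep = ~(d2 < ((radii[js] + probe) ** 2)[None, :]).any(axis=1)
            alive = alive[keep]
            if len(alive) == 0:
                break
        out[i] = len(alive) / n_sphere_points * 4.0 * np.pi * shell_r**2
    return out


@dataclass
class AccessibilityProfile:
    """Per-residue SASA at a stated probe radius.

    ``table`` columns: segment, chain, res_index, aa, axial_nm, sasa
    (chain-summed per residue), and when chain averaging is applied,
    ``sasa_chain_avg`` keyed by (segment, aligned_index).
    """

    probe_radius: float
    table: pd.DataFrame
    chain_averaged: bool = True
    highlight_threshold: float = SASA_HIGHLIGHT_THRESHOLD
    frame: int | None = None

    def accessible(self) -> pd.DataFrame:
        """Residues above the display threshold."""
        col = "sasa_chain_avg" if self.chain_averaged else "sasa"
        return self.table[self.table[col] > self.highlight_threshold]

    def mean_over(self, mask: pd.Series | np.ndarray) -> float:
        col = "sasa_chain_avg" if self.chain_averaged else "sasa"
        return float(self.table.loc[mask, col].mean())


def _chain_average(table: pd.DataFrame, model: FibrilModel) -> pd.DataFrame:
    """Average the three chains of each helix at the same sequence position.

    The one-residue stagger between chains is a placement artifact; the
    statistic averages the two alpha1 and the alpha2 chain at the same
    sequence index (all three chains keep G-X-X' phase, so glycine
    positions average glycines and stay near zero in the profile).
    """
    tab = table.copy()
    tab["aligned_index"] = tab["res_index"]
    grp = tab.groupby(["segment", "aligned_index"])["sasa"].mean()
    tab = tab.join(grp.rename("sasa_chain_avg"),
                   on=["segment", "aligned_index"])
    return tab


def residue_profile(
    model: FibrilModel,
    probe: float = LARGE_PROBE,
    restrict: str = "surface_A",
    coords: np.ndarray | None = None,
    n_sphere_points: int = N_SPHERE_POINTS,
    frame: int | None = None,
    target_mask: np.ndarray | None = None,
) -> AccessibilityProfile:
    """Chain-averaged per-residue SASA profile.

    ``restrict`` selects which residues are *reported* (the representative
    microfibril of surface A or B, or ``all``); every atom still occludes.
    ``target_mask`` further narrows the computed atoms (e.g. one motif).
    """
    if restrict not in ("surface_A", "surface_B", "all"):
        raise ValueError(f"unknown restrict {restrict!r}")
    atoms = model.atoms
    if coords is None:
        coords = model.coords()
    sel = model.mask(protein_only=True)
    if restrict != "all":
        sel &= model.mask(layer=restrict, representative=True)
    if target_mask is not None:
        sel &= target_mask
    targets = np.flatnonzero(sel)
    if len(targets) == 0:
        raise ValueError("selection reports no residues")
    area = shrake_rupley(
        coords, atoms["radius"].to_numpy(float), probe,
        n_sphere_points=n_sphere_points, targets=targets,
    )
    sub = atoms.iloc[targets].copy()
    sub["atom_sasa"] = area[targets]
    table = (
        sub.groupby(["segment", "chain", "res_index"], as_index=False)
        .agg(aa=("aa", "first"), axial=("z", "mean"),
             sasa=("atom_sasa", "sum"))
    )
    table["axial_nm"] = np.mod(table.pop("axial"), model.cell.c) / 10.0
    table = _chain_average(table, model)
    return AccessibilityProfile(
        probe_radius=probe, table=table, chain_averaged=True, frame=frame,
    )


def accessibility_timeseries(
    traj,
    probe: float = LARGE_PROBE,
    target_mask: np.ndarray | None = None,
    frames: list[int] | None = None,
    restrict: str = "surface_A",
    n_sphere_points: int = N_SPHERE_POINTS,
) -> list[AccessibilityProfile]:
    """Per-frame accessibility profiles for selected target residues.

    Waters are excluded from occlusion (accessibility is a protein-surface
    property).  Returns one profile per requested frame, each tagged with
    its frame number; the per-target maximum-accessibility frame is
    available from ``max_accessibility_frame``.
    """
    frames = list(range(traj.n_frames)) if frames is None else frames
    model = traj.topology
    prot = (model.atoms["role"] != "water").to_numpy()
    prot_rows = np.flatnonzero(prot)
    prot_model = FibrilModel(
        atoms=model.atoms.iloc[prot_rows].reset_index(drop=True),
        cell=model.cell, geometry=model.geometry,
        preset_name=model.preset_name,
    )
    tmask = target_mask[prot_rows] if target_mask is not None else None
    out = []
    for t in frames:
        coords = traj.coords[t][prot_rows].astype(float)
        out.append(residue_profile(
            prot_model, probe=probe, coords=coords, frame=t,
            restrict=restrict, n_sphere_points=n_sphere_points,
            target_mask=tmask,
        ))
    return out


def max_accessibility_frame(profiles: list[AccessibilityProfile]) -> int:
    """Frame at which the mean chain-averaged SASA of the profiles' targets
    peaks."""
    means = [p.table["sasa_chain_avg"].mean() for p in profiles]
    k = int(np.argmax(means))
    return profiles[k].frame if profiles[k].frame is not None else k
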