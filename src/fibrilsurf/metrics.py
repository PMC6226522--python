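"""Layer- and segment-resolved trajectory RMSD and RMSF.

RMSD is computed per frame against frame 0 over a Calpha selection, by
default without superposition: the lattice restrains segment termini in a
fixed frame, so absolute displacement is meaningful.  With ``fit="rigid"``
an optimal (Kabsch) superposition is applied first.  RMSF is the
per-residue fluctuation about the windowed mean position over an
equilibrated tail of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MetricSeries:
    """One RMSD (vs frame) or RMSF (vs residue) series."""

    kind: str                 # "rmsd" | "rmsf"
    selection: dict
    values: np.ndarray        # A
    index: np.ndarray         # frame numbers or residue keys
    equilibration_window: tuple[int, int] | None = None
    residue_axial_nm: np.ndarray | None = None

    @property
    def final(self) -> float:
        return float(self.values[-1])

    def to_frame(self) -> pd.DataFrame:
        col = "frame" if self.kind == "rmsd" else "residue"
        df = pd.DataFrame({col: self.index, "value_A": self.values})
        if self.residue_axial_nm is not None:
            df["axial_nm"] = self.residue_axial_nm
        return df


def _selection_rows(traj, selection: dict | np.ndarray) -> np.ndarray:
    if isinstance(selection, np.ndarray):
        rows = (np.flatnonzero(selection)
                if selection.dtype == bool else selection)
    else:
        rows = np.flatnonzero(traj.topology.mask(**selection))
    if len(rows) == 0:
        raise ValueError("empty selection")
    return rows


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing |R P + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def rmsd_series(
    traj,
    selection: dict | np.ndarray,
    fit: str = "none",
) -> MetricSeries:
    """Per-frame Calpha RMSD against frame 0.

    ``selection`` is either a boolean/index array over topology atoms or a
    dict of keyword filters for ``FibrilModel.mask`` (a ``name="CA"``
    filter is added when absent).
    """
    if fit not in ("none", "rigid"):
        raise ValueError("fit must be 'none' or 'rigid'")
    if isinstance(selection, dict):
        selection = {"name": "CA", **selection}
    rows = _selection_rows(traj, selection)
    ref = traj.coords[0][rows].astype(float)
    vals = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        X = traj.coords[t][rows].astype(float)
        if fit == "rigid":
            R, tr = kabsch(X, ref)
            X = X @ R.T + tr
        vals[t] = np.sqrt(np.mean(np.sum((X - ref) ** 2, axis=1)))
    return MetricSeries(
        kind="rmsd",
        selection=(selection if isinstance(selection, dict)
                   else {"rows": len(rows)}),
        values=vals,
        index=np.arange(traj.n_frames),
    )


def rmsf_profile(
    traj,
    selection: dict | np.ndarray,
    equilibration_fraction: float = 0.4,
) -> MetricSeries:
    """Per-residue RMSF about the mean position over the equilibrated tail.

    The first ``equilibration_fraction`` of frames is discarded; at least
    two frames must remain.  Residues are keyed and ordered by axial
    distance from the SRU N-terminus so that surface and core profiles can
    be compared position by position.
    """
    if isinstance(selection, dict):
        selection = {"name": "CA", **selection}
    rows = _selection_rows(traj, selection)
    t0 = int(np.floor(equilibration_fraction * traj.n_frames))
    if traj.n_frames - t0 < 2:
        raise ValueError("equilibration window leaves fewer than two frames")
    X = traj.coords[t0:, rows, :].astype(float)
    mean = X.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    atoms = traj.topology.atoms.iloc[rows]
    axial = atoms["z"].to_numpy(float) / 10.0
    order = np.argsort(axial, kind="stable")
    keys = np.array([
        f"{s}/{ch}{ri}" for s, ch, ri in
        zip(atoms["segment"], atoms["chain"], atoms["res_index"])
    ])
    return MetricSeries(
        kind="rmsf",
        selection=(selection if isinstance(selection, dict)
                   else {"rows": len(rows)}),
        values=rmsf[order],
        index=keys[order],
        equilibration_window=(t0, traj.n_frames),
        residue_axial_nm=axial[order],
    )


def paired_layer_excess(
    traj,
    segment: str | tuple[str, ...] | None = None,
    equilibration_fraction: float = 0.4,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Surface-A minus core RMSF, paired by axial position bins.

    Returns one row per axial bin with the mean RMSF of each layer and the
    surface excess -- the quantity whose peaks localize the most mobile
    segments of the interaction surface.
    """
    out = {}
    for layer in ("surface_A", "core"):
        series = rmsf_profile(
            traj,
            {"layer": layer, "segment": segment, "representative": True},
            equilibration_fraction,
        )
        out[layer] = (series.residue_axial_nm, series.values)
    lo = min(a.min() for a, _ in out.values())
    hi = max(a.max() for a, _ in out.values())
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    rows = []
    for b in range(n_bins):
        rec = {"axial_nm": 0.5 * (edges[b] + edges[b + 1])}
        for layer, (a, v) in out.items():
            m = (a >= edges[b]) & (a < edges[b + 1])
            rec[layer] = float(v[m].mean()) if m.any() else np.nan
        rec["excess"] = rec["surface_A"] - rec["core"]
        rows.append(rec)
    return pd.DataFrame(rows)
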