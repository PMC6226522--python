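"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available --
all-pairs loops, dense grids, closed forms -- staying independent of the
vectorized implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_hbonds(coords, donors, acceptors, antecedent, res_id,
                       chain_code, res_index, is_backbone,
                       max_distance, min_angle):
    """All-pairs geometric H-bond detection; returns set of (i, j) with
    i < j."""
    bonds = set()
    for d in donors:
        for a in acceptors:
            if a == d or res_id[d] == res_id[a]:
                continue
            if (chain_code[d] == chain_code[a]
                    and abs(res_index[d] - res_index[a]) == 1
                    and is_backbone[d] and is_backbone[a]):
                continue
            if np.linalg.norm(coords[d] - coords[a]) > max_distance:
                continue
            if antecedent[d] >= 0:
                v1 = coords[antecedent[d]] - coords[d]
                v2 = coords[a] - coords[d]
                cosang = (v1 @ v2) / (np.linalg.norm(v1)
                                      * np.linalg.norm(v2) + 1e-12)
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang < min_angle:
                    continue
            bonds.add((min(d, a), max(d, a)))
    return bonds


def double_loop_rmsd(ref, frame):
    """RMSD by explicit accumulation over atoms and coordinates."""
    total = 0.0
    n = len(ref)
    for i in range(n):
        for k in range(3):
            diff = frame[i][k] - ref[i][k]
            total += diff * diff
    return (total / n) ** 0.5


def double_loop_rmsf(frames):
    """Per-atom RMSF by explicit loops about the mean position."""
    n_frames = len(frames)
    n_atoms = len(frames[0])
    out = []
    for i in range(n_atoms):
        mean = [0.0, 0.0, 0.0]
        for t in range(n_frames):
            for k in range(3):
                mean[k] += frames[t][i][k] / n_frames
        acc = 0.0
        for t in range(n_frames):
            for k in range(3):
                d = frames[t][i][k] - mean[k]
                acc += d * d
        out.append((acc / n_frames) ** 0.5)
    return np.array(out)


def grid_sasa(coords, radii, probe, resolution=0.2):
    """Volumetric-grid SASA oracle.

    Marks every grid voxel whose centre is an allowed probe position
    (outside all inflated atom spheres), then scores each atom's shell
    points by whether their nearest voxel is allowed.  Independent of the
    Shrake-Rupley neighbour logic; agreement is expected at the few-percent
    level set by the grid resolution.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    pad = radii.max() + 2 * probe + 2 * resolution
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + resolution, resolution)
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # per-voxel coverage count and (one) covering atom id: a shell point of
    # atom k lies exactly on k's own inflated sphere, so coverage by k
    # alone must not read as occlusion
    cover_count = np.zeros(len(pts), dtype=np.int32)
    cover_id = np.full(len(pts), -1, dtype=np.int32)
    for k, (c, r) in enumerate(zip(coords, radii)):
        inside = np.sum((pts - c) ** 2, axis=1) < (r + probe) ** 2
        cover_count[inside] += 1
        cover_id[inside] = k
    shape = gx.shape

    def voxel_ok(p, self_id):
        idx = np.rint((p - lo) / resolution).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        flat = np.ravel_multi_index(
            (idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        cnt = cover_count[flat]
        return (cnt == 0) | ((cnt == 1) & (cover_id[flat] == self_id))

    # dense deterministic shell sampling
    n_pts = 2000
    i = np.arange(n_pts) + 0.5
    phi = np.arccos(1 - 2 * i / n_pts)
    theta = np.pi * (1 + 5**0.5) * i
    unit = np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)
    out = np.zeros(len(coords))
    for k, (c, r) in enumerate(zip(coords, radii)):
        shell = c + (r + probe) * unit
        out[k] = voxel_ok(shell, k).mean() * 4 * np.pi * (r + probe) ** 2
    return out
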