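"""Synthetic surface-reconstruction dynamics and D-banded height profiles.

This module is the desk-scale stand-in for a long explicit-solvent MD run of
the 3a3b fibril model.  It does not integrate any force field; instead it
*constructs* trajectories that realize, geometrically, the three
conformational modes observed at the fibril surface --

1. longitudinal (N-terminal) translation of the C-telopeptide,
2. downward (-b) displacement of D5 in the overlap region, with a transient
   outward a-bulge, and
3. inward (-a) contraction of the surface layer in the gap region,

-- on top of a thermal background, together with scheduled formation of
inter-helix protein-protein contacts and expulsion of bound surface waters.
The modes act on the surface-A layer only; core and surface-B receive the
thermal background alone.

Thermal motion is modelled as two parts.  A *collective drift*: a spatially
smooth random direction field (correlation length ``drift_length``) whose
magnitude is a deterministic envelope ramped in time, capturing the slow
low-frequency displacement of whole helix stretches without stretching
local bond geometry.  And a small fast per-atom jitter (``thermal_sigma``).
Because the drift magnitude is deterministic, layer-resolved RMSD values
concentrate tightly across seeds while the displacement *direction* remains
random.  Three residues at each D-segment terminus (telopeptides excepted)
are restrained by an envelope that pins them near their start positions,
mirroring the termini restraints a fibril-periodic simulation would apply.

The calibrated preset (``calibrated_schedule``) sizes the contact schedule
to +0.169 protein-protein H-bonds per residue, the water expulsion to
-0.142 protein-water H-bonds per residue, and calibrates drift and D5-drop
amplitudes so the final-frame D5 Calpha RMSD is ~4 A in the core layer and
~12 A in the surface-A layer, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .afm import HeightProfile
from .config import FibrilGeometry
from .hbonds import HBondCriteria, _Roles, detect_hbonds
from .lattice import FibrilModel

NS_PER_FRAME = 2.5  # cosmetic frame-time label


# ---------------------------------------------------------------------------
# schedule containers
# ---------------------------------------------------------------------------

@dataclass
class Contact:
    """One scheduled protein-protein contact: ``mover`` is displaced until it
    sits at ``target_offset`` from the donor's (deterministic) position, at
    or before ``frame``."""

    donor: int
    mover: int
    target_offset: np.ndarray
    frame: int


@dataclass
class WaterSite:
    """A bound surface water anchored to a protein atom; removed from the
    surface at ``expel_frame`` (None = persists).  ``n_bonds`` is the number
    of protein-water H-bonds the site forms in the starting structure (the
    anchor bond plus any close secondary partners)."""

    anchor: int
    offset: np.ndarray
    expel_frame: int | None = None
    n_bonds: int = 1


@dataclass
class ModeSchedule:
    """Amplitudes, schedules and noise parameters for one trajectory."""

    n_frames: int = 101
    telopeptide_shift: float = 20.0   # A toward the N-terminus (-c)
    d5_drop: float = 8.0              # A along -b, D5 surface-A
    d5_bulge: float = 3.0             # A transient +a oscillation
    gap_contraction: float = 4.0      # A inward (-a), surface gap region
    gap_breathing: float = 0.35       # transient oscillation fraction of it
    thermal_sigma: float = 0.08       # A fast per-atom jitter
    drift_amplitude: float = 4.0      # A collective drift magnitude
    drift_length: float = 150.0       # A drift correlation length
    packing_strain: float = 0.0       # surface-layer a-compression (strain)
    seed: int = 42
    contacts: list[Contact] = field(default_factory=list)
    waters: list[WaterSite] = field(default_factory=list)

    def validate(self, model: FibrilModel) -> None:
        n = len(model.atoms)
        for c in self.contacts:
            if not (0 <= c.donor < n and 0 <= c.mover < n):
                raise ValueError("contact references an absent atom")
        for w in self.waters:
            if not 0 <= w.anchor < n:
                raise ValueError("water anchor references an absent atom")
        for v in (self.telopeptide_shift, self.d5_drop, self.d5_bulge,
                  self.gap_contraction, self.thermal_sigma,
                  self.drift_amplitude, self.packing_strain):
            if not np.isfinite(v):
                raise ValueError("schedule amplitudes must be finite")


@dataclass
class Trajectory:
    """Frames of coordinates sharing one FibrilModel topology."""

    topology: FibrilModel
    coords: np.ndarray                 # (n_frames, n_atoms, 3), A
    frame_times: np.ndarray            # ns, nominal
    presence: np.ndarray | None = None  # (n_frames, n_atoms) bool

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def restraint_envelope(atoms: pd.DataFrame) -> np.ndarray:
    """Per-atom displacement envelope implementing the termini restraints.

    Three residues at each end of every D-segment (per chain, per SRU copy)
    are held near their start positions; the envelope ramps from 0.05 there
    to 1 for interior residues.  Telopeptides are exempt (envelope 1).
    """
    env = np.ones(len(atoms))
    prot = (atoms["role"] != "water").to_numpy()
    sub = atoms[prot]
    key = pd.MultiIndex.from_arrays(
        [sub["copy_a"], sub["copy_b"], sub["segment"], sub["chain"]]
    )
    res = sub["res_index"].to_numpy()
    telo = sub["is_telopeptide"].to_numpy()
    codes = key.factorize()[0]
    # residue rank from each end of its group, vectorized over (group, res)
    uniq_pairs, inv = np.unique(np.stack(
        [codes[~telo], res[~telo]]), axis=1, return_inverse=True)
    g_of = uniq_pairs[0]
    n_per_group = np.bincount(g_of)
    first_slot = np.concatenate([[0], np.cumsum(n_per_group)[:-1]])
    rank = np.arange(len(g_of)) - first_slot[g_of]
    d_end = np.minimum(rank, n_per_group[g_of] - 1 - rank)
    e_helical = 0.05 + 0.95 * np.clip((d_end - 2) / 6.0, 0.0, 1.0)
    e = np.ones(len(sub))
    e[~telo] = e_helical[inv]
    env[prot] = e
    return env


def _direction_field(
    coords: np.ndarray, length: float, rng: np.random.Generator,
    n_bumps: int = 48,
) -> np.ndarray:
    """Smooth random unit-vector field evaluated at ``coords``."""
    lo = coords.min(axis=0) - length / 2
    hi = coords.max(axis=0) + length / 2
    centers = rng.uniform(lo, hi, size=(n_bumps, 3))
    weights = rng.normal(size=(n_bumps, 3))
    g = np.zeros_like(coords)
    for c, w in zip(centers, weights):
        phi = np.exp(-np.sum((coords - c) ** 2, axis=1) / (2 * length**2))
        g += phi[:, None] * w[None, :]
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    fallback = np.array([0.0, 0.0, 1.0])
    g = np.where(norm > 1e-9, g / np.maximum(norm, 1e-9), fallback)
    return g


def _mode_displacement(model: FibrilModel, schedule: ModeSchedule):
    """Final-frame mode displacement U, transient bulge shape B, and the
    magnitude of the D5 modes alone (used to locally suppress the thermal
    drift where the telopeptide shift / D5 drop dominate the motion)."""
    atoms = model.atoms
    n = len(atoms)
    U = np.zeros((n, 3))
    Bb = np.zeros((n, 3))
    Gb = np.zeros((n, 3))
    cell_c = model.cell.c
    f = model.geometry.d5_fraction
    z = atoms["z"].to_numpy()
    layer_a = (atoms["layer"] == "surface_A").to_numpy()
    telo = atoms["is_telopeptide"].to_numpy()
    seg = atoms["segment"].to_numpy()
    region = atoms["region"].to_numpy()
    prot = (atoms["role"] != "water").to_numpy()

    d5_mag = np.zeros(n)

    # (1) C-telopeptide longitudinal translation (D5 telopeptide = C-telo)
    m = layer_a & telo & (seg == "D5") & prot
    U[m, 2] -= schedule.telopeptide_shift
    d5_mag[m] += schedule.telopeptide_shift

    # (2) D5 drop along -b, with transient +a bulge, tapered to zero at the
    # segment ends
    m = layer_a & ~telo & (seg == "D5") & prot
    s = np.sin(np.pi * np.clip(z[m] / (f * cell_c), 0.0, 1.0))
    U[m, 1] -= schedule.d5_drop * s
    Bb[m, 0] += schedule.d5_bulge * s
    d5_mag[m] += schedule.d5_drop * s

    # (3) gap-region contraction toward the core, stronger for rows closer
    # to the surface
    offsets = {k: v[0] for k, v in _segment_a_offsets(model).items()}
    a_max = max(offsets.values()) if offsets else 1.0
    gap_lo = f * cell_c
    gap_len = cell_c - gap_lo
    m = layer_a & ~telo & (region == "gap") & prot
    if m.any():
        w = np.array([offsets.get(s_, 0.0) / a_max for s_ in seg[m]])
        genv = np.sin(np.pi * np.clip((z[m] - gap_lo) / gap_len, 0.0, 1.0))
        U[m, 0] -= schedule.gap_contraction * w * genv
        # the contracting gap surface breathes about its trajectory; the
        # oscillation vanishes at the first and final frames
        Gb[m, 0] -= (schedule.gap_breathing * schedule.gap_contraction
                     * w * genv)

    # (4) surface packing strain: every triple helix in the two surface
    # layers tightens radially about its own axis (positive strain) or
    # loosens (negative), modelling the winding compaction that accompanies
    # water loss.  The calibrated preset solves this strain so the
    # realized net H-bond change matches its per-residue quota.
    if schedule.packing_strain != 0.0:
        lam = schedule.packing_strain
        x = atoms["x"].to_numpy()
        y = atoms["y"].to_numpy()
        local = _segment_a_offsets(model)
        surf = atoms["layer"].isin(["surface_A", "surface_B"]).to_numpy()
        cell_a, cell_b = model.cell.a, model.cell.b
        copy_a = atoms["copy_a"].to_numpy()
        copy_b = atoms["copy_b"].to_numpy()
        m = surf & prot & ~telo
        cax = np.array([local[s_][0] for s_ in seg[m]]) + copy_a[m] * cell_a
        cay = np.array([local[s_][1] for s_ in seg[m]]) + copy_b[m] * cell_b
        U[m, 0] -= lam * (x[m] - cax)
        U[m, 1] -= lam * (y[m] - cay)
    return U, Bb, Gb, d5_mag


def _segment_a_offsets(model: FibrilModel) -> dict[str, tuple[float, float]]:
    """Mean local (a, b) centre of each segment within its cell."""
    atoms = model.atoms
    out = {}
    one = atoms[(atoms["copy_a"] == 0) & (atoms["copy_b"] == 0)]
    for s, grp in one.groupby("segment"):
        out[s] = (float(grp["x"].mean()), float(grp["y"].mean()))
    return out


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

class _GenState:
    """Precomputed, seed-deterministic state shared by every frame."""

    def __init__(self, model: FibrilModel, schedule: ModeSchedule, T: int):
        rng = np.random.default_rng(schedule.seed)
        topo_atoms = model.atoms.copy().reset_index(drop=True)
        self.n_prot = n_prot = len(topo_atoms)
        self.waters = waters = schedule.waters
        if waters:
            anchor_rows = np.array([w.anchor for w in waters])
            wdf = topo_atoms.iloc[anchor_rows][
                ["segment", "region", "layer", "copy_a", "copy_b"]
            ].reset_index(drop=True)
            wdf["chain"] = "W"
            wdf["res_index"] = np.arange(1, len(waters) + 1)
            wdf["aa"] = "-"
            wdf["name"] = "W"
            wdf["element"] = "O"
            wdf["role"] = "water"
            wdf["radius"] = 1.4
            wdf["is_glycine"] = False
            wdf["is_telopeptide"] = False
            off = np.stack([w.offset for w in waters])
            anc = topo_atoms.iloc[anchor_rows][["x", "y", "z"]].to_numpy(float)
            wxyz = anc + off
            wdf["x"], wdf["y"], wdf["z"] = wxyz[:, 0], wxyz[:, 1], wxyz[:, 2]
            topo_atoms = pd.concat(
                [topo_atoms, wdf[topo_atoms.columns]], ignore_index=True
            )
        self.topology = FibrilModel(atoms=topo_atoms, cell=model.cell,
                                    geometry=model.geometry,
                                    preset_name=model.preset_name)
        self.X0 = X0 = topo_atoms[["x", "y", "z"]].to_numpy(float)
        self.N = N = len(X0)
        self.T = T
        self.schedule = schedule
        self.env = env = restraint_envelope(topo_atoms)

        U = np.zeros((N, 3))
        Bb = np.zeros((N, 3))
        Gb = np.zeros((N, 3))
        d5_mag = np.zeros(N)
        (U[:n_prot], Bb[:n_prot], Gb[:n_prot],
         d5_mag[:n_prot]) = _mode_displacement(model, schedule)
        U[:n_prot] *= env[:n_prot, None]
        Bb[:n_prot] *= env[:n_prot, None]
        Gb[:n_prot] *= env[:n_prot, None]
        d5_mag[:n_prot] *= env[:n_prot]
        self.U, self.Bb, self.Gb = U, Bb, Gb

        # collective drift: deterministic magnitude, smooth random
        # direction; suppressed where the D5 modes dominate the motion
        dhat = _direction_field(X0, schedule.drift_length, rng)
        suppress = np.exp(-d5_mag / max(schedule.drift_amplitude, 1e-9))
        self.drift = (schedule.drift_amplitude * env * suppress)[:, None] * dhat
        self._rng = rng  # positioned after the drift draws

        self.anchor_of = np.arange(N)
        if waters:
            self.anchor_of[n_prot:] = np.array([w.anchor for w in waters])

        self.mover_rows = np.array([c.mover for c in schedule.contacts],
                                   dtype=int)
        self.donor_rows = np.array([c.donor for c in schedule.contacts],
                                   dtype=int)
        self.engage = np.array([c.frame for c in schedule.contacts],
                               dtype=float)
        if len(self.mover_rows):
            self.orig_off = X0[self.mover_rows] - X0[self.donor_rows]
            self.targ_off = np.stack(
                [c.target_offset for c in schedule.contacts])

    def next_jitter(self) -> np.ndarray:
        return self._rng.normal(0.0, 1.0, size=(self.N, 3)) * (
            self.schedule.thermal_sigma * self.env
        )[:, None]

    def frame_coords(self, t: int, jitter: np.ndarray) -> np.ndarray:
        T, sched = self.T, self.schedule
        r = smoothstep(t / (T - 1))
        bulge_t = np.sin(np.pi * t / (T - 1))
        breath_t = r * np.sin(4 * np.pi * t / (T - 1))
        disp_det = (r * self.U + bulge_t * self.Bb
                    + breath_t * self.Gb + r * self.drift)
        disp = disp_det + jitter
        n_prot = self.n_prot
        if self.waters:
            # waters track their anchor's full displacement
            disp[n_prot:] = (disp[self.anchor_of[n_prot:]]
                             + 0.5 * jitter[n_prot:])
        if len(self.mover_rows):
            # contact movers track their donor, closing in on the target
            u = np.clip(np.divide(t, np.maximum(self.engage, 1.0)), 0.0, 1.0)
            cur = self.orig_off + (
                self.targ_off - self.orig_off) * smoothstep(u)[:, None]
            disp[self.mover_rows] = (
                self.X0[self.donor_rows] + disp_det[self.donor_rows]
                + jitter[self.donor_rows] + cur - self.X0[self.mover_rows]
            )
        return self.X0 + disp

    def frame_presence(self, t: int) -> np.ndarray:
        present = np.ones(self.N, dtype=bool)
        for w_i, w in enumerate(self.waters):
            if w.expel_frame is not None and t >= w.expel_frame:
                present[self.n_prot + w_i] = False
        return present


def generate_trajectory(
    model: FibrilModel,
    schedule: ModeSchedule,
    n_frames: int | None = None,
) -> Trajectory:
    """Realize a ModeSchedule as an explicit trajectory.

    Deterministic for a fixed seed.  With all amplitudes zero every frame
    equals frame 0.
    """
    schedule.validate(model)
    T = n_frames or schedule.n_frames
    if T < 2:
        raise ValueError("need at least two frames")
    state = _GenState(model, schedule, T)
    coords = np.empty((T, state.N, 3))
    presence = np.ones((T, state.N), dtype=bool)
    for t in range(T):
        coords[t] = state.frame_coords(t, state.next_jitter())
        presence[t] = state.frame_presence(t)
    return Trajectory(
        topology=state.topology,
        coords=coords,
        frame_times=np.arange(T) * NS_PER_FRAME,
        presence=presence if state.waters else None,
    )


def _boundary_frames(model: FibrilModel, schedule: ModeSchedule):
    """First- and final-frame coordinates (and topology/presence) with the
    exact noise streams a full generation would use -- cheap evaluation for
    schedule calibration."""
    T = schedule.n_frames
    state = _GenState(model, schedule, T)
    first = state.frame_coords(0, state.next_jitter())
    for _ in range(1, T - 1):
        state.next_jitter()
    last = state.frame_coords(T - 1, state.next_jitter())
    return state.topology, first, last, state.frame_presence(T - 1)


# ---------------------------------------------------------------------------
# calibrated schedule
# ---------------------------------------------------------------------------

def _cone_directions(axis: np.ndarray) -> np.ndarray:
    """Candidate bond directions within 45 deg of the donor axis, so the
    antecedent-donor-acceptor angle keeps a 15 deg margin over the 135 deg
    complement of the criterion."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    dirs = [axis]
    for tilt in (np.radians(15.0), np.radians(30.0), np.radians(42.0),
                 np.radians(52.0)):
        for az in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            dirs.append(
                np.cos(tilt) * axis
                + np.sin(tilt) * (np.cos(az) * e1 + np.sin(az) * e2)
            )
    return np.asarray(dirs)


def _find_contacts(
    model: FibrilModel,
    n_contacts: int,
    rng: np.random.Generator,
    criteria: HBondCriteria,
    bond_distance: float = 2.2,
    obstacles: np.ndarray | None = None,
    allowed_movers: np.ndarray | None = None,
    existing: list[Contact] | None = None,
) -> tuple[list[Contact], set[int]]:
    """Pick donor/mover pairs for scheduled inter-helix contact formation.

    Constraints: both partners in a surface layer (A or B -- both outer
    faces pack and reconstruct; the core stays untouched), different triple
    helices, at least one sidechain partner (inter-helix backbone-backbone
    bonds must stay rare), mover unbonded at frame 0, and a clash-free
    target position that creates exactly one new bond.  A donor may host up
    to two movers (targets are kept mutually separated); ``obstacles`` are
    extra positions (e.g. placed waters) the targets must stay clear of.
    """
    atoms = model.atoms
    coords = model.coords()
    roles = _Roles(atoms)
    b0 = detect_hbonds(coords, model, criteria)
    bonded = np.zeros(len(atoms), dtype=bool)
    if len(b0):
        bonded[b0["i"].to_numpy()] = True
        bonded[b0["j"].to_numpy()] = True

    surface = atoms["layer"].isin(["surface_A", "surface_B"]).to_numpy()
    telo = atoms["is_telopeptide"].to_numpy()
    name = atoms["name"].to_numpy()
    ok_base = surface & ~telo
    # movers must be free to travel: never draft the pinned terminal
    # residues (the three at each D-segment end)
    unrestrained = restraint_envelope(atoms) > 0.1

    donors_sc = np.flatnonzero(ok_base & roles.donor & roles.is_sidechain)
    donors_n = np.flatnonzero(ok_base & (name == "N"))
    donors_telo = np.flatnonzero(
        surface & telo & roles.donor
    )
    mover_ok = ok_base & ~bonded & unrestrained
    if allowed_movers is None:
        pref, rest = mover_ok, np.zeros_like(mover_ok)
    else:
        # prefer atoms whose departure forfeits nothing (e.g. atoms still
        # unbonded at the final frame of a dry run); fall back to the rest
        pref = mover_ok & allowed_movers
        rest = mover_ok & ~allowed_movers
    movers_sc = np.flatnonzero(pref & roles.acceptor & roles.is_sidechain)
    movers_o = np.flatnonzero(pref & (name == "O"))
    movers_sc2 = np.flatnonzero(rest & roles.acceptor & roles.is_sidechain)
    movers_o2 = np.flatnonzero(rest & (name == "O"))

    tree_all = cKDTree(coords)
    da_rows = np.flatnonzero(roles.donor | roles.acceptor)
    tree_da = cKDTree(coords[da_rows])
    obs_tree = (cKDTree(obstacles) if obstacles is not None
                and len(obstacles) else None)

    contacts: list[Contact] = []
    used: set[int] = set()
    donor_uses: dict[int, int] = {}
    placed_targets: list[np.ndarray] = []
    if existing:
        # continue from a previous round: honour its pairings and targets
        contacts.extend(existing)
        for c in existing:
            used.add(int(c.mover))
            donor_uses[int(c.donor)] = donor_uses.get(int(c.donor), 0) + 1
            placed_targets.append(coords[c.donor] + c.target_offset)

    def is_gray(q: int, t: np.ndarray) -> bool:
        """A secondary partner in the borderline shell around the distance
        cutoff would toggle under thermal motion; targets avoid those.
        Solid close partners (inside the cutoff with margin) are fine: the
        preset's packing-strain bisection works on realized counts and
        absorbs whatever extra bonds they contribute."""
        dist = float(np.linalg.norm(coords[q] - t))
        return (criteria.max_distance - 0.1) < dist <= (
            criteria.max_distance + 0.3)

    def try_pairs(donors, movers, max_n):
        if not len(donors) or not len(movers):
            return
        mover_tree = cKDTree(coords[movers])
        order = rng.permutation(len(donors))
        for oi in order:
            if len(contacts) >= max_n:
                return
            d = donors[oi]
            if d in used or donor_uses.get(d, 0) >= 6:
                continue
            ante = roles.antecedent[d]
            vd = coords[d] - coords[ante]
            nv = np.linalg.norm(vd)
            if nv < 1e-6:
                continue
            cand = mover_tree.query_ball_point(coords[d], 18.0)
            rng.shuffle(cand)
            mover = -1
            for ci in cand:
                m = movers[ci]
                # a mover must not already serve as mover or donor elsewhere
                if m in used or m in donor_uses or m == d:
                    continue
                if roles.helix_id[m] == roles.helix_id[d]:
                    continue
                if np.linalg.norm(coords[m] - coords[d]) < 3.2:
                    continue
                mover = m
                break
            if mover < 0:
                continue
            for direction in _cone_directions(vd / nv):
                t = coords[d] + bond_distance * direction
                close = tree_all.query_ball_point(t, 1.8)
                if any(c != d for c in close):
                    continue
                if obs_tree is not None and obs_tree.query_ball_point(t, 2.0):
                    continue
                if placed_targets and np.min(np.linalg.norm(
                        np.asarray(placed_targets) - t, axis=1)) < 3.0:
                    continue
                near_da = tree_da.query_ball_point(
                    t, criteria.max_distance + 0.45)
                if any(
                    da_rows[c] != d and da_rows[c] != mover
                    and is_gray(da_rows[c], t)
                    for c in near_da
                ):
                    continue
                contacts.append(Contact(
                    donor=int(d), mover=int(mover),
                    target_offset=t - coords[d],
                    frame=0,
                ))
                used.add(int(mover))
                donor_uses[d] = donor_uses.get(d, 0) + 1
                placed_targets.append(t)
                break

    try_pairs(donors_sc, movers_o, n_contacts)
    try_pairs(donors_sc, movers_sc, n_contacts)
    try_pairs(donors_n, movers_sc, n_contacts)
    if len(movers_sc2) or len(movers_o2):
        try_pairs(donors_sc, movers_o2, n_contacts)
        try_pairs(donors_sc, movers_sc2, n_contacts)
        try_pairs(donors_n, movers_sc2, n_contacts)
    # last resort: telopeptide donors (open space above the surfaces);
    # movers track their donor, so the bond survives the telopeptide shift
    if len(contacts) < n_contacts:
        for mv in (movers_o, movers_sc, movers_o2, movers_sc2):
            try_pairs(donors_telo, mv, n_contacts)
    used.update(donor_uses)
    return contacts[:n_contacts], used


_WATER_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)],
    dtype=float,
)
_WATER_DIRECTIONS /= np.linalg.norm(_WATER_DIRECTIONS, axis=1, keepdims=True)


def _place_waters(
    model: FibrilModel,
    n_target: int,
    rng: np.random.Generator,
    bond_length: float = 2.65,
    obstacles: np.ndarray | None = None,
) -> list[WaterSite]:
    """Anchor bound waters to surface-layer backbone oxygens.

    Each water is placed so it hydrogen-bonds to exactly one protein atom
    (its anchor); expelled waters therefore remove exactly one
    protein-water bond each.
    """
    atoms = model.atoms
    coords = model.coords()
    roles = _Roles(atoms)
    layer_a = (atoms["layer"] == "surface_A").to_numpy()
    telo = atoms["is_telopeptide"].to_numpy()
    name = atoms["name"].to_numpy()
    anchors = np.flatnonzero(
        layer_a & ~telo
        & ((name == "O") | (roles.acceptor & roles.is_sidechain))
    )
    tree_all = cKDTree(coords)
    da_rows = np.flatnonzero(roles.donor | roles.acceptor)
    tree_da = cKDTree(coords[da_rows])

    # a water donates with no angle gate, so every donor/acceptor within
    # reach of a site bonds it; each site records its nominal starting bond
    # count (anchor plus close partners).  The expulsion bookkeeping uses
    # *measured* per-water bond counts later, so placement only needs to be
    # sterically sound.
    obs_tree = (cKDTree(obstacles) if obstacles is not None
                and len(obstacles) else None)
    sites: list[WaterSite] = []
    placed: list[np.ndarray] = []
    order = rng.permutation(len(anchors))
    for oi in order:
        if len(sites) >= n_target:
            break
        a = anchors[oi]
        for direction in _WATER_DIRECTIONS:
            pos = coords[a] + bond_length * direction
            if tree_all.query_ball_point(pos, 2.3):
                continue
            if obs_tree is not None and obs_tree.query_ball_point(pos, 3.0):
                continue
            if placed and np.min(
                np.linalg.norm(np.asarray(placed) - pos, axis=1)
            ) < 3.2:
                continue
            near = [da_rows[c] for c in tree_da.query_ball_point(pos, 3.0)]
            sites.append(WaterSite(anchor=int(a),
                                   offset=bond_length * direction,
                                   n_bonds=max(1, len(near))))
            placed.append(pos)
            break
    return sites


def water_positions(model: FibrilModel,
                    sites: list[WaterSite]) -> np.ndarray:
    coords = model.coords()
    return np.stack([coords[w.anchor] + w.offset for w in sites]) \
        if sites else np.empty((0, 3))


def _calibrated_schedule_once(
    model: FibrilModel,
    seed: int = 42,
    n_frames: int = 101,
    pp_delta: float = 0.169,
    pw_delta: float = 0.142,
    rmsd_surface: float = 12.0,
    rmsd_core: float = 4.0,
    telopeptide_shift: float = 20.0,
    gap_contraction: float = 4.0,
    d5_bulge: float = 3.0,
    thermal_sigma: float = 0.08,
    drift_length: float = 150.0,
    criteria: HBondCriteria | None = None,
) -> ModeSchedule:
    """The calibrated preset: encode the printed trajectory outcomes.

    The contact schedule is sized to ``pp_delta`` net new protein-protein
    bonds per residue and the water expulsion to ``pw_delta`` per residue.
    The collective-drift amplitude is calibrated so the final-frame core
    D5 Calpha RMSD equals ``rmsd_core``; the D5 drop amplitude so the
    surface-A D5 RMSD equals ``rmsd_surface`` (in expectation over the
    random drift direction).
    """
    criteria = criteria or HBondCriteria()
    rng = np.random.default_rng(seed)
    atoms = model.atoms
    n_res = model.n_residues
    pp_quota = int(round(pp_delta * n_res))
    pw_quota = int(round(pw_delta * n_res))

    env = restraint_envelope(atoms)
    ca = (atoms["name"] == "CA").to_numpy()
    rep = (atoms["copy_b"] == model.representative_copy_b).to_numpy()
    d5 = (atoms["segment"] == "D5").to_numpy()
    core_sel = ca & rep & d5 & (atoms["layer"] == "core").to_numpy()
    surf_sel = ca & rep & d5 & (atoms["layer"] == "surface_A").to_numpy()

    e_core = env[core_sel]
    drift_amplitude = float(
        np.sqrt(max(rmsd_core**2 - 6 * thermal_sigma**2, 0.0))
        / np.sqrt(np.mean(e_core**2))
    )

    def surface_rmsd(drop: float) -> float:
        sched = ModeSchedule(
            n_frames=n_frames, telopeptide_shift=telopeptide_shift,
            d5_drop=drop, d5_bulge=d5_bulge,
            gap_contraction=gap_contraction,
            thermal_sigma=thermal_sigma,
            drift_amplitude=drift_amplitude, drift_length=drift_length,
            seed=seed,
        )
        U, _, _, d5_mag = _mode_displacement(model, sched)
        U *= env[:, None]
        d5_mag = d5_mag * env
        umag = np.linalg.norm(U, axis=1)
        sup = np.exp(-d5_mag / max(drift_amplitude, 1e-9))
        m2 = (
            umag[surf_sel] ** 2
            + (drift_amplitude * env[surf_sel] * sup[surf_sel]) ** 2
            + 6 * thermal_sigma**2
        )
        return float(np.sqrt(np.mean(m2)))

    lo_k, hi_k = 0.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo_k + hi_k)
        if surface_rmsd(mid) < rmsd_surface:
            lo_k = mid
        else:
            hi_k = mid
    d5_drop = 0.5 * (lo_k + hi_k)

    # --- net-quota calibration -------------------------------------------
    # Waters are placed first and included in every evaluation, so the
    # seeded noise streams are identical across the dry run, the contact
    # sizing iteration, the strain bisection and the final trajectory.
    # The modes and thermal background make and break borderline bonds of
    # their own; the dry boundary evaluation measures that churn for this
    # seed, the contact schedule is sized to the residual by fixed-point
    # iteration on the realized final-frame count (movers preferentially
    # drawn from atoms unbonded at both ends of the dry run, so their
    # departure forfeits nothing), and the surface packing strain closes
    # the remaining gap exactly.
    waters = _place_waters(
        model, n_target=int(pw_quota * 1.5) + max(4, pw_quota // 10),
        rng=rng,
    )
    water_xyz = water_positions(model, waters)

    def make(strain: float, contacts: list[Contact]) -> ModeSchedule:
        return ModeSchedule(
            n_frames=n_frames, telopeptide_shift=telopeptide_shift,
            d5_drop=d5_drop, d5_bulge=d5_bulge,
            gap_contraction=gap_contraction, thermal_sigma=thermal_sigma,
            drift_amplitude=drift_amplitude, drift_length=drift_length,
            packing_strain=strain, seed=seed, contacts=contacts,
            waters=[WaterSite(w.anchor, w.offset, None, w.n_bonds)
                    for w in waters],
        )

    roles_cache: dict = {}

    def boundary(strain: float, contacts: list[Contact]):
        topo, first, last, _ = _boundary_frames(model,
                                                make(strain, contacts))
        if "roles" not in roles_cache:
            roles_cache["roles"] = _Roles(topo.atoms)
        roles = roles_cache["roles"]
        bf = detect_hbonds(first, topo, criteria, _roles=roles)
        bl = detect_hbonds(last, topo, criteria, _roles=roles)
        return bf, bl

    bd_first, bd_last = boundary(0.0, [])
    churn = int(bd_last["is_pp"].sum()) - int(bd_first["is_pp"].sum())
    free_at_last = np.ones(len(model.atoms), dtype=bool)
    rows = np.concatenate([bd_last["i"].to_numpy(),
                           bd_last["j"].to_numpy()])
    free_at_last[rows[rows < len(model.atoms)]] = False

    # Aim the contact count slightly ABOVE the quota: the strain lever has
    # more reach on the expansion (bond-breaking) side than on the
    # compression side, so a mild overshoot is the safe side to land on.
    n_request = max(0, pp_quota - churn) + 60
    contacts: list[Contact] = []
    realized = churn
    for round_ in range(8):
        contacts, _ = _find_contacts(
            model, n_request,
            np.random.default_rng(seed + 1 + 1000 * round_), criteria,
            allowed_movers=free_at_last, obstacles=water_xyz,
            existing=contacts if round_ else None,
        )
        bf, bl = boundary(0.0, contacts)
        realized = int(bl["is_pp"].sum()) - int(bf["is_pp"].sum())
        overshoot = realized - pp_quota
        if -40 <= overshoot <= 220:
            break
        if overshoot > 220:
            # too many: rebuild from scratch with a smaller request
            n_request = max(0, n_request - (overshoot - 100))
            contacts = []
        else:
            n_request = max(len(contacts), n_request) - overshoot + 60
    lo, hi = max(2, int(0.08 * n_frames)), n_frames - 2
    eng = np.sort(np.linspace(lo, hi, len(contacts)).round().astype(int)) \
        if contacts else np.array([], dtype=int)
    for c, f in zip(contacts, eng):
        c.frame = int(f)

    # --- packing strain: close the residual exactly ----------------------
    pp_first = int(bf["is_pp"].sum())
    target_pp = pp_first + pp_quota

    def pp_final(strain: float) -> int:
        _, bl = boundary(strain, contacts)
        return int(bl["is_pp"].sum())

    f_lo, f_hi = -0.18, 0.30
    v_lo, v_hi = pp_final(f_lo), pp_final(f_hi)
    if not (v_lo <= target_pp <= v_hi):
        # clamp to the nearest endpoint when the residual is a small
        # fraction of the quota; otherwise the preset genuinely cannot be
        # realized on this model
        gap = min(abs(target_pp - v_lo), abs(target_pp - v_hi))
        if gap <= max(40, int(0.08 * pp_quota)):
            strain = f_lo if abs(target_pp - v_lo) < abs(
                target_pp - v_hi) else f_hi
        else:
            raise RuntimeError(
                f"packing-strain range cannot reach the H-bond quota "
                f"({v_lo}..{v_hi} vs target {target_pp})"
            )
    else:
        # regula falsi on the (noisy, near-monotone) realized count
        a, fa = f_lo, v_lo - target_pp
        b, fb = f_hi, v_hi - target_pp
        strain = 0.0
        for _ in range(10):
            m = a - fa * (b - a) / max(fb - fa, 1)
            m = float(np.clip(m, a + 1e-4, b - 1e-4))
            fm = pp_final(m) - target_pp
            if abs(fm) <= 3:
                strain = m
                break
            if fm < 0:
                a, fa = m, fm
            else:
                b, fb = m, fm
            strain = m

    # --- water expulsion sizing from measured final-frame bonds ----------
    b_first, b_last = boundary(strain, contacts)
    pw_drift = int(b_last["is_pw"].sum()) - int(b_first["is_pw"].sum())
    bonds_to_remove = max(0, pw_quota + pw_drift)
    n_prot = len(model.atoms)
    per_water = np.zeros(len(waters), dtype=int)
    pw = b_last[b_last["is_pw"]]
    for i, j in pw[["i", "j"]].itertuples(index=False):
        row = j if j >= n_prot else i
        per_water[row - n_prot] += 1
    order = rng.permutation(len(waters))
    expel_idx, acc = [], 0
    for k in order:
        if acc >= bonds_to_remove:
            break
        expel_idx.append(k)
        acc += int(per_water[k])
    if acc < bonds_to_remove:
        raise RuntimeError(
            f"placed waters carry {acc} final-frame bonds, "
            f"need {bonds_to_remove}"
        )
    exf = np.sort(np.linspace(lo, hi, len(expel_idx)).round().astype(int))
    schedule = make(strain, contacts)
    for k, f in zip(expel_idx, exf):
        schedule.waters[k].expel_frame = int(f)
    return schedule


def calibrated_schedule(
    model: FibrilModel,
    seed: int = 42,
    max_realizations: int = 8,
    **kwargs,
) -> ModeSchedule:
    """Build the calibrated schedule (see ``_calibrated_schedule_once``).

    Rarely, a thermal realization breaks so many borderline bonds that the
    lattice cannot host enough new packing contacts to meet the net H-bond
    quota.  Such realizations are rejected and the next one derived from
    ``seed`` is calibrated instead; the procedure is deterministic for a
    given seed.  The returned schedule's ``seed`` field holds the accepted
    realization.
    """
    last_error: Exception | None = None
    for attempt in range(max_realizations):
        trial = int((seed + attempt * 7919) % (2**31 - 1))
        try:
            return _calibrated_schedule_once(model, seed=trial, **kwargs)
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(
        f"no feasible thermal realization in {max_realizations} attempts "
        f"from seed {seed}: {last_error}"
    )


# ---------------------------------------------------------------------------
# synthetic D-banded AFM height profiles
# ---------------------------------------------------------------------------

def generate_height_profile(
    geom: FibrilGeometry,
    step_height: float = 4.1,
    n_periods: int = 10,
    noise_sigma: float = 0.3,
    tilt: float = 2.0,
    seed: int = 0,
    dx: float = 1.0,
    edge_width: float = 2.0,
) -> HeightProfile:
    """Synthetic D-banded AFM height profile (positions/heights in nm).

    A two-level waveform with high plateaus of fractional width
    ``d5_fraction`` (the overlap region), period ``d_period``, amplitude
    ``step_height``; edges smoothed over ``edge_width`` nm, plus a linear
    tilt (nm per micrometre) and Gaussian noise.
    """
    if step_height <= 0:
        raise ValueError("step_height must be positive")
    if n_periods < 2:
        raise ValueError("need at least two periods")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    period = geom.d_period / 10.0  # A -> nm
    x = np.arange(0.0, n_periods * period, dx)
    phase = np.mod(x, period) / period
    square = (phase < geom.d5_fraction).astype(float)
    if edge_width > 0:
        square = gaussian_filter1d(square, edge_width / dx, mode="wrap")
    h = step_height * square
    h = h + tilt * x / 1000.0
    if noise_sigma > 0:
        h = h + rng.normal(0.0, noise_sigma, size=x.shape)
    return HeightProfile(
        positions=x, heights=h,
        metadata={"source": "synthetic", "period_nm": period,
                  "step_height_nm": step_height, "seed": seed},
    )
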