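"""Geometric hydrogen-bond detection and classified per-frame tallies.

The reduced-atom model carries no explicit hydrogens, so a bond is scored on
heavy-atom geometry alone: donor...acceptor distance below a cutoff and the
angle at the donor, measured between the donor's antecedent atom (CA for
backbone N and for sidechain pseudo-atoms) and the acceptor, above a minimum.
Water pseudo-atoms act as both donor and acceptor with no angle requirement.

Bonds are classified the way fibril-packing analyses need them:
protein-protein vs protein-water; within one triple helix vs between triple
helices (a triple helix is one D-segment of one SRU copy, i.e. the labels
(copy_a, copy_b, segment)); backbone-backbone vs sidechain-involved.  Counts
are normalized per protein residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import HBOND_MAX_DISTANCE, HBOND_MIN_ANGLE, POLAR_SIDECHAINS
from .lattice import FibrilModel


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = HBOND_MAX_DISTANCE  # A, donor...acceptor
    min_angle: float = HBOND_MIN_ANGLE        # degrees at the donor

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must lie in (0, 180]")


@dataclass
class HBondTally:
    """Per-frame classified H-bond counts and per-residue normalizations."""

    n_residues: int
    n_pp: np.ndarray
    n_pw: np.ndarray
    n_pp_intra_helix: np.ndarray
    n_pp_inter_helix: np.ndarray
    n_backbone_backbone: np.ndarray
    n_sidechain_involved: np.ndarray
    n_pp_inter_sidechain: np.ndarray = field(default=None)

    def per_residue(self, series: np.ndarray) -> np.ndarray:
        return series / float(self.n_residues)

    @property
    def delta_pp_per_residue(self) -> float:
        """Last-frame minus first-frame protein-protein bonds per residue."""
        return float((self.n_pp[-1] - self.n_pp[0]) / self.n_residues)

    @property
    def delta_pw_per_residue(self) -> float:
        return float((self.n_pw[-1] - self.n_pw[0]) / self.n_residues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.n_pp)),
            "pp": self.n_pp, "pw": self.n_pw,
            "pp_intra_helix": self.n_pp_intra_helix,
            "pp_inter_helix": self.n_pp_inter_helix,
            "backbone_backbone": self.n_backbone_backbone,
            "sidechain_involved": self.n_sidechain_involved,
        })


class _Roles:
    """Precomputed donor/acceptor machinery for one topology."""

    def __init__(self, atoms: pd.DataFrame):
        n = len(atoms)
        name = atoms["name"].to_numpy()
        role = atoms["role"].to_numpy()
        aa = atoms["aa"].to_numpy()
        self.is_water = role == "water"
        polar_sc = (name == "SC") & np.isin(aa, list(POLAR_SIDECHAINS))
        self.donor = (name == "N") | polar_sc | self.is_water
        self.acceptor = (name == "O") | polar_sc | self.is_water

        # residue and helix identity codes
        res_key = pd.MultiIndex.from_arrays(
            [atoms["copy_a"], atoms["copy_b"], atoms["segment"],
             atoms["chain"], atoms["res_index"]]
        )
        self.res_id = res_key.factorize()[0]
        helix_key = pd.MultiIndex.from_arrays(
            [atoms["copy_a"], atoms["copy_b"], atoms["segment"]]
        )
        self.helix_id = helix_key.factorize()[0]
        self.res_index = atoms["res_index"].to_numpy()
        self.chain_code = pd.factorize(
            pd.MultiIndex.from_arrays(
                [atoms["copy_a"], atoms["copy_b"], atoms["segment"],
                 atoms["chain"]]
            )
        )[0]
        self.is_backbone = role == "backbone"
        self.is_sidechain = role == "sidechain"

        # antecedent: the CA of the donor's own residue (waters have none)
        ca_row_of_res = np.full(self.res_id.max() + 1, -1, dtype=int)
        ca_rows = np.flatnonzero(name == "CA")
        ca_row_of_res[self.res_id[ca_rows]] = ca_rows
        self.antecedent = np.where(
            self.is_water, -1, ca_row_of_res[self.res_id]
        )


def _candidate_pairs(
    coords: np.ndarray, roles: _Roles, criteria: HBondCriteria,
    present: np.ndarray | None,
) -> np.ndarray:
    donor_rows = np.flatnonzero(roles.donor if present is None
                                else roles.donor & present)
    acc_rows = np.flatnonzero(roles.acceptor if present is None
                              else roles.acceptor & present)
    if len(donor_rows) == 0 or len(acc_rows) == 0:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(coords[acc_rows])
    hits = tree.query_ball_point(coords[donor_rows], criteria.max_distance)
    pairs = [
        (d, acc_rows[j])
        for d, js in zip(donor_rows, hits)
        for j in js
        if acc_rows[j] != d
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def detect_hbonds(
    coords: np.ndarray,
    model: FibrilModel | pd.DataFrame,
    criteria: HBondCriteria | None = None,
    present: np.ndarray | None = None,
    _roles: _Roles | None = None,
) -> pd.DataFrame:
    """All hydrogen bonds in one coordinate frame.

    Returns a table of unordered atom pairs (columns ``i``, ``j`` with
    i < j) with classification columns.  A pair is bonded if *either*
    donor->acceptor direction satisfies the distance and angle criteria;
    enumeration order therefore cannot change the count.  Covalent
    neighbours are excluded (same residue, or backbone atoms of adjacent
    residues in one chain).
    """
    atoms = model.atoms if isinstance(model, FibrilModel) else model
    criteria = criteria or HBondCriteria()
    roles = _roles if _roles is not None else _Roles(atoms)
    if np.isnan(coords).any():
        raise ValueError("NaN coordinates")
    pairs = _candidate_pairs(coords, roles, criteria, present)
    if len(pairs):
        d, a = pairs[:, 0], pairs[:, 1]
        # covalent exclusions
        same_res = roles.res_id[d] == roles.res_id[a]
        adjacent_bb = (
            (roles.chain_code[d] == roles.chain_code[a])
            & (np.abs(roles.res_index[d] - roles.res_index[a]) == 1)
            & roles.is_backbone[d] & roles.is_backbone[a]
        )
        pairs = pairs[~(same_res | adjacent_bb)]
    if len(pairs):
        d, a = pairs[:, 0], pairs[:, 1]
        ante = roles.antecedent[d]
        has_ante = ante >= 0
        v1 = coords[np.where(has_ante, ante, 0)] - coords[d]
        v2 = coords[a] - coords[d]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = ~has_ante | (angle >= criteria.min_angle)
        pairs = pairs[ok]
    # dedupe unordered pairs
    if len(pairs):
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        uniq = np.unique(lo.astype(np.int64) * len(atoms) + hi)
        lo = uniq // len(atoms)
        hi = uniq % len(atoms)
    else:
        lo = hi = np.array([], dtype=int)
    out = pd.DataFrame({"i": lo, "j": hi})
    w_lo = roles.is_water[lo]
    w_hi = roles.is_water[hi]
    out["is_pw"] = w_lo ^ w_hi          # exactly one water partner
    out["is_pp"] = ~w_lo & ~w_hi        # water-water pairs are neither class
    out["intra_helix"] = roles.helix_id[lo] == roles.helix_id[hi]
    out["backbone_backbone"] = (
        roles.is_backbone[lo] & roles.is_backbone[hi] & out["is_pp"]
    )
    out["sidechain_involved"] = out["is_pp"] & ~out["backbone_backbone"]
    return out


def tally_series(
    traj,
    criteria: HBondCriteria | None = None,
) -> HBondTally:
    """Classified per-frame H-bond tallies for a trajectory."""
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    criteria = criteria or HBondCriteria()
    atoms = traj.topology.atoms
    roles = _Roles(atoms)
    cols = {
        k: np.zeros(traj.n_frames)
        for k in ("pp", "pw", "intra", "inter", "bb", "sc", "inter_sc")
    }
    for t in range(traj.n_frames):
        present = traj.presence[t] if traj.presence is not None else None
        bonds = detect_hbonds(traj.coords[t].astype(float), traj.topology,
                              criteria, present=present, _roles=roles)
        pp = bonds["is_pp"]
        cols["pp"][t] = pp.sum()
        cols["pw"][t] = bonds["is_pw"].sum()
        cols["intra"][t] = (pp & bonds["intra_helix"]).sum()
        cols["inter"][t] = (pp & ~bonds["intra_helix"]).sum()
        cols["bb"][t] = bonds["backbone_backbone"].sum()
        cols["sc"][t] = bonds["sidechain_involved"].sum()
        cols["inter_sc"][t] = (
            bonds["sidechain_involved"] & ~bonds["intra_helix"]
        ).sum()
    n_res = traj.topology.n_residues
    return HBondTally(
        n_residues=n_res,
        n_pp=cols["pp"], n_pw=cols["pw"],
        n_pp_intra_helix=cols["intra"], n_pp_inter_helix=cols["inter"],
        n_backbone_backbone=cols["bb"], n_sidechain_involved=cols["sc"],
        n_pp_inter_sidechain=cols["inter_sc"],
    )
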