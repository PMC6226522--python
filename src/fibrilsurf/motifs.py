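"""Integrin-binding motif scanning and mapping onto the fibril lattice.

The minimal collagen-binding integrin recognition sequence is of the form
G-X-X'-G-E-X'' (a glutamate two triplets after an anchoring glycine); the
high-affinity alpha1-chain instance studied here is GQRGER.  The motif
grammar is deliberately small: literal residue letters plus the wildcard
``X``.  Hits are mapped to D-segment, axial position (nm from the SRU
N-terminus) and gap/overlap region via the lattice labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .lattice import FibrilModel

#: the canonical minimal integrin motif, Glu fixed at position 5
GXXGEX = "GXXGEX"


@dataclass
class MotifHit:
    pattern: str
    chain: str                  # alpha1 | alpha2
    start: int                  # 1-based, inclusive
    end: int                    # 1-based, inclusive
    matched: str
    segment: str | None = None
    axial_nm: float | None = None
    region: str | None = None
    affinity_class: str | None = None


def _check_pattern(pattern: str) -> None:
    if not pattern:
        raise ValueError("empty motif pattern")
    bad = set(pattern) - set("ACDEFGHIKLMNPQRSTVWYOX")
    if bad:
        raise ValueError(f"invalid motif letters {bad}")


def scan_motifs(
    sequence: str,
    pattern: str = GXXGEX,
    chain: str = "alpha1",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of the motif in a chain sequence.

    ``X`` matches any residue; other letters are literal.  Ranges are
    1-based inclusive.
    """
    _check_pattern(pattern)
    n = len(pattern)
    hits = []
    for i in range(len(sequence) - n + 1):
        window = sequence[i:i + n]
        if all(p == "X" or p == w for p, w in zip(pattern, window)):
            hits.append(MotifHit(pattern=pattern, chain=chain,
                                 start=i + 1, end=i + n, matched=window))
    return hits


def motif_regex(pattern: str) -> str:
    """Equivalent regular expression (used by the scan's cross-check)."""
    _check_pattern(pattern)
    return "".join("." if p == "X" else re.escape(p) for p in pattern)


def locate_in_fibril(hit: MotifHit, model: FibrilModel) -> MotifHit:
    """Fill in segment, axial position and region from the lattice.

    The hit's chain maps to builder chain A (alpha1) or C (alpha2); the
    location is resolved on the surface-A representative copy (every SRU
    copy carries the same sequence, so the location is copy-independent).
    """
    chain_id = "A" if hit.chain.startswith("alpha1") else "C"
    atoms = model.atoms
    sel = (
        model.mask(chain=chain_id, name="CA")
        & atoms["res_index"].between(hit.start, hit.end).to_numpy()
    )
    if sel.sum() == 0:
        raise ValueError(
            f"motif residues {hit.start}-{hit.end} absent from chain "
            f"{chain_id}"
        )
    if "copy_b" in atoms.columns and atoms["copy_b"].nunique() > 1:
        rep = model.representative_copy_b
        sel &= (atoms["copy_a"] == atoms["copy_a"].max()).to_numpy()
        sel &= (atoms["copy_b"] == rep).to_numpy()
    sub = atoms[sel]
    hit.segment = sub["segment"].mode().iloc[0]
    hit.axial_nm = float(np.mod(sub["z"], model.cell.c).mean() / 10.0)
    hit.region = sub["region"].mode().iloc[0]
    return hit


def motif_atom_mask(
    model: FibrilModel,
    hit: MotifHit,
    layer: str = "surface_A",
    representative: bool = True,
    all_chains: bool = True,
) -> np.ndarray:
    """Atom mask for the motif's residues in one lattice copy.

    With ``all_chains`` the same sequence positions of all three chains are
    included, matching the chain-averaging convention of the accessibility
    statistic.
    """
    atoms = model.atoms
    m = model.mask(layer=layer, representative=representative)
    if all_chains:
        m &= atoms["res_index"].between(hit.start, hit.end).to_numpy()
    else:
        chain_id = "A" if hit.chain.startswith("alpha1") else "C"
        m &= model.mask(chain=chain_id)
        m &= atoms["res_index"].between(hit.start, hit.end).to_numpy()
    return m
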