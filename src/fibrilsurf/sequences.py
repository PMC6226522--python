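"""Collagen chain sequences: synthetic stand-in chains and (G-X-X')n builders.

The bundled alpha1/alpha2 chains are *synthetic stand-ins* for the mature
type I collagen chains: they reproduce the architectural features the lattice
and accessibility analyses depend on -- an uninterrupted (G-X-X')n triple-
helical domain flanked by non-helical N-/C-telopeptides, a collagen-like
residue composition rich in proline (P) and hydroxyproline (O), and the
high-affinity integrin motif GQRGER placed on the alpha1 chain so that it
falls on D-segment D4 at the edge of the overlap region, underneath the
folded-back C-telopeptide -- but they are not the natural sequences.

Hydroxyproline is encoded as the one-letter code ``O``.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

from Bio import SeqIO

from .config import AMINO_ACIDS, Preset

# triplet pools for the helical domain; cycled deterministically.  Roughly
# 44% of X/X' positions carry polar sidechains, echoing the charged/hydroxyl
# content of the natural chains.
_ALPHA1_TRIPLETS = (
    "GPO", "GER", "GAO", "GPK", "GQO", "GDR", "GSP", "GPA",
    "GEO", "GKA", "GNO", "GPQ", "GLO", "GAR", "GPS", "GVE",
)
_ALPHA2_TRIPLETS = (
    "GPO", "GAV", "GER", "GPS", "GKO", "GDA", "GQP", "GPO",
    "GNA", "GLE", "GAO", "GRP", "GSO", "GPE", "GKV", "GAQ",
)

# telopeptides: non-triplet termini, kept glycine-free so motif scans see
# only the helical domain.
_N_TELO = "SQSVQDEKSANVDQEFSQTAVKDES"
_C_TELO = "DEKSADNVQFSATEVKDQSPAEFKV"

#: the high-affinity integrin alphaI-domain motif carried by the alpha1 chain
GQRGER = "GQRGER"


def triplet_domain(n_residues: int, pool: tuple[str, ...]) -> str:
    """Deterministic (G-X-X')n domain of ``n_residues`` from a triplet pool."""
    n_triplets = -(-n_residues // 3)
    seq = "".join(pool[i % len(pool)] for i in range(n_triplets))
    return seq[:n_residues]


def synthetic_chain(
    helical_residues: int,
    n_telo: int,
    c_telo: int,
    pool: tuple[str, ...] = _ALPHA1_TRIPLETS,
    motif: str | None = None,
    motif_helical_index: int | None = None,
) -> str:
    """Assemble a full synthetic chain: N-telo + (G-X-X')n + C-telo.

    ``motif_helical_index`` is 0-based within the helical domain and must be
    a multiple of 3 so the motif's leading G keeps triplet phase.
    """
    helical = triplet_domain(helical_residues, pool)
    if motif is not None:
        i = motif_helical_index
        if i is None or i % 3 != 0:
            raise ValueError("motif_helical_index must be a multiple of 3")
        if i + len(motif) > helical_residues:
            raise ValueError("motif does not fit in the helical domain")
        helical = helical[:i] + motif + helical[i + len(motif):]
    chain = _N_TELO[:n_telo] + helical + _C_TELO[:c_telo]
    bad = set(chain) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letters {bad}")
    return chain


def chains_for_preset(preset: Preset) -> tuple[str, str, str]:
    """(alpha1, alpha1, alpha2) chains sized for a lattice preset.

    The GQRGER motif is placed on the alpha1 chains so that it lands on D4
    just inside the overlap edge, within the axial span covered by the
    folded-back C-telopeptide of the neighbouring D5 segment.
    """
    rise = preset.helix.axial_rise
    d = preset.geometry.d_period
    f = preset.geometry.d5_fraction
    # In SRU axial coordinates a D4 residue at monomer axial z sits at
    # z - 3D, while the folded C-telopeptide of D5 covers
    # [helical_end - c_telo*rise - 4D, helical_end - 4D].  The motif must lie
    # inside that covered span and end before the overlap/gap junction f*D.
    helical_end = (preset.helical_residues - 1) * rise
    lo_sru = (helical_end - preset.c_telo * rise) - 4.0 * d
    hi_sru = min(f * d, helical_end - 4.0 * d) - len(GQRGER) * rise
    k_lo = (3.0 * d + lo_sru) / rise
    k_hi = (3.0 * d + hi_sru) / rise
    k = int(k_hi)
    k -= k % 3  # keep the leading G in triplet phase
    if k + 1 < k_lo:
        raise ValueError("preset too short to host the GQRGER motif on D4")
    a1 = synthetic_chain(
        preset.helical_residues, preset.n_telo, preset.c_telo,
        pool=_ALPHA1_TRIPLETS, motif=GQRGER, motif_helical_index=k,
    )
    a2 = synthetic_chain(
        preset.helical_residues, preset.n_telo, preset.c_telo,
        pool=_ALPHA2_TRIPLETS,
    )
    return a1, a1, a2


def bundled_chains() -> dict[str, str]:
    """Read the bundled synthetic alpha1/alpha2 full-length chains (FASTA)."""
    out = {}
    for stem in ("col1a1_synthetic", "col1a2_synthetic"):
        text = (
            importlib.resources.files("fibrilsurf") / "data" / f"{stem}.fasta"
        ).read_text()
        rec = next(SeqIO.parse(StringIO(text), "fasta"))
        out[stem.split("_")[0]] = str(rec.seq)
    return out
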