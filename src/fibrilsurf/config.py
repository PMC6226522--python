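"""Package-wide configuration: helix parameters, fibril presets, atom radii.

All lengths are in Angstrom internally; reports use nm.  Two lattice presets
ship: ``schematic`` (D-period 670 A = 67 nm, the textbook banding length) and
``3hr2`` (unit cell 678 x 27 x 40 A, the fibre-diffraction calibration).  A
``reduced`` preset with the same cross-section but a short axial repeat is the
substrate for the synthetic-dynamics analyses.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field

import yaml

# ---------------------------------------------------------------------------
# atom radii (A).  Reduced-atom model: backbone N/CA/C/O plus one sidechain
# pseudo-atom per non-glycine residue.  Sidechain radii approximate the girth
# of the full sidechain as a single united sphere.
# ---------------------------------------------------------------------------

BACKBONE_RADII: dict[str, float] = {"N": 1.55, "CA": 1.90, "C": 1.70, "O": 1.52}

SIDECHAIN_RADII: dict[str, float] = {
    "A": 2.10, "R": 2.80, "N": 2.45, "D": 2.40, "C": 2.30,
    "Q": 2.60, "E": 2.55, "H": 2.65, "I": 2.60, "L": 2.60,
    "K": 2.75, "M": 2.65, "F": 2.75, "P": 2.45, "S": 2.20,
    "T": 2.40, "W": 2.90, "Y": 2.80, "V": 2.45, "O": 2.50,
}

#: residues whose sidechain pseudo-atom acts as both H-bond donor and acceptor.
#: 'O' is hydroxyproline (hydroxyl group).
POLAR_SIDECHAINS = frozenset("STNQDEKRHYO")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"O"}

BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

# default Shrake-Rupley sampling
N_SPHERE_POINTS = 960
WATER_PROBE = 1.4
LARGE_PROBE = 8.0
SASA_HIGHLIGHT_THRESHOLD = 15.0  # A^2, display threshold for "accessible"

# geometric H-bond criteria (heavy-atom; reduced model carries no hydrogens,
# so the angle is measured at the donor via its antecedent atom)
HBOND_MAX_DISTANCE = 3.0   # A donor...acceptor
HBOND_MIN_ANGLE = 120.0    # degrees, antecedent-donor-acceptor


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixParams:
    """Geometric free parameters of the idealized collagen triple helix.

    The 7/2 helical symmetry (twist of -102.857 deg per residue, axial rise
    2.86 A) is the classic fibre-diffraction value for collagen; the radius
    places the Calpha track 1.5 A off the common axis.  Glycine Calpha sits
    closer to the axis (``glycine_radius_scale``) so that the glycine of each
    G-X-X' triplet points to the helix centre.
    """

    axial_rise: float = 2.86
    twist: float = -720.0 / 7.0
    helix_radius: float = 1.5
    chain_stagger: tuple[int, int, int] = (0, 1, 2)
    sidechain_offset: float = 3.0
    glycine_radius_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.axial_rise <= 0:
            raise ValueError("axial_rise must be positive")
        if self.helix_radius < 0:
            raise ValueError("helix_radius must be non-negative")
        if sorted(self.chain_stagger) != [0, 1, 2]:
            raise ValueError("chain_stagger must assign distinct staggers 0,1,2")


@dataclass(frozen=True)
class FibrilGeometry:
    """Axial architecture of the D-period."""

    d_period: float = 670.0
    d5_fraction: float = 0.46
    n_segments: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.d5_fraction < 1:
            raise ValueError("d5_fraction must lie in (0, 1)")
        if self.d_period <= 0:
            raise ValueError("d_period must be positive")

    @property
    def overlap_interval(self) -> tuple[float, float]:
        """Axial window [0, f*D) where all five segments are present."""
        return (0.0, self.d5_fraction * self.d_period)

    @property
    def gap_interval(self) -> tuple[float, float]:
        return (self.d5_fraction * self.d_period, self.d_period)

    @property
    def overlap_length(self) -> float:
        return self.d5_fraction * self.d_period

    @property
    def gap_length(self) -> float:
        return (1.0 - self.d5_fraction) * self.d_period


@dataclass(frozen=True)
class UnitCell:
    """SRU unit cell; a = surface normal (depth), b = lateral, c = axial."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit cell dimensions must be positive")


@dataclass(frozen=True)
class Preset:
    """One named lattice configuration."""

    name: str
    geometry: FibrilGeometry
    cell: UnitCell
    helix: HelixParams
    helical_residues: int
    n_telo: int
    c_telo: int
    #: quasihexagonal (a, b) offsets of the five D-segment helix axes
    segment_offsets: dict[str, tuple[float, float]]
    #: folded-back C-telopeptide: lift along +a and lateral drift along b
    fold_lift: float = 6.0
    fold_drift_b: float = -13.5

    @property
    def chain_length(self) -> int:
        return self.n_telo + self.helical_residues + self.c_telo


def _build_preset(name: str, raw: dict) -> Preset:
    helix_kwargs = {
        k: raw[k]
        for k in ("axial_rise", "twist", "helix_radius", "sidechain_offset",
                  "glycine_radius_scale")
        if k in raw
    }
    if "chain_stagger" in raw:
        helix_kwargs["chain_stagger"] = tuple(raw["chain_stagger"])
    return Preset(
        name=name,
        geometry=FibrilGeometry(
            d_period=raw["d_period"], d5_fraction=raw.get("d5_fraction", 0.46)
        ),
        cell=UnitCell(a=raw["cell_a"], b=raw["cell_b"], c=raw["cell_c"]),
        helix=HelixParams(**helix_kwargs),
        helical_residues=raw["helical_residues"],
        n_telo=raw["n_telo"],
        c_telo=raw["c_telo"],
        segment_offsets={k: tuple(v) for k, v in raw["segment_offsets"].items()},
        fold_lift=raw.get("fold_lift", 6.0),
        fold_drift_b=raw.get("fold_drift_b", -13.5),
    )


def load_presets() -> dict[str, Preset]:
    """Load the bundled YAML preset file."""
    text = (
        importlib.resources.files("fibrilsurf") / "data" / "presets.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {name: _build_preset(name, cfg) for name, cfg in raw.items()}


def get_preset(name: str) -> Preset:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def preset_with(preset: Preset, **overrides) -> Preset:
    """Return a copy of ``preset`` with selected fields replaced."""
    return dataclasses.replace(preset, **overrides)
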