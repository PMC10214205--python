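"""Closed-form thermodynamics of surface crowding.

A soluble macromolecule binding to a receptor buried in a crowded surface
layer pays a steric free-energy penalty ΔU.  Adsorption thermodynamics link
that penalty to the measurable shift in the effective dissociation constant,

    ΔU = kB·T · ln(KD / KD0),

where KD is measured on the crowded surface and KD0 on a bare reference
surface.  The same penalty can be read as mechanical work against the osmotic
pressure Π of the surface brush, ΔU ≈ Π·Veff, with Veff the volume the probe
excludes inside the layer.  This module implements those relations, a
scaling-theory (Alexander–de Gennes) estimate of the insertion penalty, the
Debye screening length, and the avidity-corrected effective affinity of a
bivalent antibody on a sparse antigen surface.

Energies are expressed in units of kB·T throughout; conversions to SI happen
only inside :func:`osmotic_pressure`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .constants import DEFAULT_TEMPERATURE_K, E_CHARGE, EPS0, KB, NA, NM3_TO_M3
from .errors import ConfigurationError, DomainError

__all__ = [
    "Anchor",
    "Flexibility",
    "VeffConvention",
    "SensorSpec",
    "CrowderSpec",
    "BufferSpec",
    "CrowdingEnergy",
    "OsmoticPressureEstimate",
    "AntibodyBindingModel",
    "crowding_energy_from_kd_ratio",
    "kd_ratio_from_energy",
    "osmotic_pressure",
    "excluded_volume",
    "grafting_spacing",
    "debye_length",
    "surface_density_from_copies",
    "round_sig",
    "brush_insertion_penalty",
    "effective_antibody_kd",
]


class Anchor(str, enum.Enum):
    """How a sensor attaches to the membrane."""

    cholesterol = "cholesterol"
    biotin_dna = "biotin_dna"
    none = "none"


class Flexibility(str, enum.Enum):
    flexible = "flexible"
    semiflexible = "semiflexible"


class VeffConvention(str, enum.Enum):
    """Convention turning a probe diameter d into an excluded volume.

    ``sphere_diameter``: (π/6)d³, the probe's own volume.
    ``sphere_radius``:   (4π/3)d³, a sphere of *radius* d — the generous
                         estimate appropriate when the probe also sweeps a
                         correlation shell inside the brush.
    ``cube``:            d³.
    """

    sphere_diameter = "sphere_diameter"
    sphere_radius = "sphere_radius"
    cube = "cube"


@dataclass(frozen=True)
class SensorSpec:
    """A soluble crowding probe modelled as an effective sphere.

    ``diameter_nm`` is the effective sphere diameter σs (e.g. 3, 5, 10 nm for
    the PEG-0.5k, dextran-10k, and dextran-40k sensors).
    """

    name: str
    diameter_nm: float
    anchor: Anchor = Anchor.none
    labeling_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise DomainError(f"sensor diameter must be positive, got {self.diameter_nm}")
        if self.labeling_ratio < 0:
            raise DomainError(f"labeling ratio must be nonnegative, got {self.labeling_ratio}")


@dataclass(frozen=True)
class CrowderSpec:
    """A grafted surface species as a bead-spring chain.

    ``beads_per_chain`` (N) beads of diameter ``bead_diameter_nm`` (σ) give a
    contour length N·σ; ``grafting_density_per_um2`` (n) counts chains per
    µm² of membrane.
    """

    name: str
    beads_per_chain: int
    bead_diameter_nm: float
    grafting_density_per_um2: float
    charge_per_bead_e: float = 0.0
    flexibility: Flexibility = Flexibility.flexible
    bending_stiffness_kBT: float = 0.0

    def __post_init__(self) -> None:
        if self.beads_per_chain < 1:
            raise DomainError(f"beads per chain must be >= 1, got {self.beads_per_chain}")
        if self.bead_diameter_nm <= 0:
            raise DomainError(f"bead diameter must be positive, got {self.bead_diameter_nm}")
        if self.grafting_density_per_um2 < 0:
            raise DomainError(
                f"grafting density must be nonnegative, got {self.grafting_density_per_um2}"
            )
        if self.bending_stiffness_kBT < 0:
            raise DomainError(
                f"bending stiffness must be nonnegative, got {self.bending_stiffness_kBT}"
            )

    @property
    def contour_length_nm(self) -> float:
        return self.beads_per_chain * self.bead_diameter_nm


@dataclass(frozen=True)
class BufferSpec:
    """Aqueous buffer: ionic strength (M), temperature (K), relative permittivity."""

    ionic_strength_M: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        for name in ("ionic_strength_M", "temperature_K", "relative_permittivity"):
            v = getattr(self, name)
            if not (v > 0):
                raise DomainError(f"{name} must be positive, got {v}")

    @property
    def debye_length_nm(self) -> float:
        return debye_length(self)


@dataclass(frozen=True)
class CrowdingEnergy:
    """A crowding penalty and the equivalent affinity shift.

    Invariant: ``delta_u_kBT == ln(kd_ratio)`` exactly.
    """

    kd_ratio: float
    delta_u_kBT: float
    se_kBT: float = 0.0

    def __post_init__(self) -> None:
        if self.se_kBT < 0:
            raise DomainError(f"standard error must be nonnegative, got {self.se_kBT}")


@dataclass(frozen=True)
class OsmoticPressureEstimate:
    """Surface osmotic pressure Π = kB·T·ΔU / Veff with its conventions."""

    pressure_Pa: float
    delta_u_kBT: float
    veff_nm3: float
    veff_convention: VeffConvention
    temperature_K: float

    @property
    def pressure_kPa(self) -> float:
        return self.pressure_Pa / 1e3


@dataclass(frozen=True)
class AntibodyBindingModel:
    """Bivalent antibody on a surface antigen.

    ``kd1_molar`` is the 3D monovalent dissociation constant of the first arm;
    ``k2_2d_per_um2`` sets the 2D crosslinking scale of the second arm; the
    effective affinity gains avidity as the antigen density rises.
    """

    kd1_molar: float
    k2_2d_per_um2: float = 14_000.0
    antigen_density_per_um2: float = 0.0

    def __post_init__(self) -> None:
        if self.kd1_molar <= 0:
            raise DomainError(f"KD1 must be positive, got {self.kd1_molar}")
        if self.k2_2d_per_um2 <= 0:
            raise DomainError(f"K2 (2D) must be positive, got {self.k2_2d_per_um2}")
        if self.antigen_density_per_um2 < 0:
            raise DomainError(
                f"antigen density must be nonnegative, got {self.antigen_density_per_um2}"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def crowding_energy_from_kd_ratio(kd_ratio: float, se_ratio: float = 0.0) -> CrowdingEnergy:
    """Convert an affinity ratio KD/KD0 into a crowding energy ΔU = ln(KD/KD0) kBT.

    ``se_ratio`` is an optional standard error on the ratio, propagated by the
    delta method (SE_ΔU = SE_ratio / ratio).
    """
    if not (kd_ratio > 0) or not math.isfinite(kd_ratio):
        raise DomainError(f"KD/KD0 must be a positive finite number, got {kd_ratio}")
    if se_ratio < 0:
        raise DomainError(f"se_ratio must be nonnegative, got {se_ratio}")
    return CrowdingEnergy(
        kd_ratio=kd_ratio,
        delta_u_kBT=math.log(kd_ratio),
        se_kBT=se_ratio / kd_ratio,
    )


def kd_ratio_from_energy(delta_u_kBT: float) -> float:
    """Inverse mapping: KD/KD0 = exp(ΔU/kBT)."""
    if not math.isfinite(delta_u_kBT):
        raise DomainError(f"crowding energy must be finite, got {delta_u_kBT}")
    return math.exp(delta_u_kBT)


def osmotic_pressure(
    delta_u_kBT: float,
    veff_nm3: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    veff_convention: VeffConvention = VeffConvention.sphere_radius,
) -> OsmoticPressureEstimate:
    """Osmotic pressure of the crowded layer, Π = kB·T·ΔU / Veff.

    ΔU is interpreted as the mechanical work to displace a volume ``veff_nm3``
    inside a layer at pressure Π.  Output in pascal.
    """
    if not (veff_nm3 > 0):
        raise DomainError(f"effective volume must be positive, got {veff_nm3}")
    if not (temperature_K > 0):
        raise DomainError(f"temperature must be positive, got {temperature_K}")
    pressure = KB * temperature_K * delta_u_kBT / (veff_nm3 * NM3_TO_M3)
    return OsmoticPressureEstimate(
        pressure_Pa=pressure,
        delta_u_kBT=delta_u_kBT,
        veff_nm3=veff_nm3,
        veff_convention=VeffConvention(veff_convention),
        temperature_K=temperature_K,
    )


def excluded_volume(
    diameter_nm: float,
    convention: VeffConvention | str = VeffConvention.sphere_radius,
) -> float:
    """Excluded volume Veff (nm³) of a probe of diameter ``diameter_nm``."""
    if not (diameter_nm > 0):
        raise DomainError(f"probe diameter must be positive, got {diameter_nm}")
    try:
        convention = VeffConvention(convention)
    except ValueError:
        valid = ", ".join(c.value for c in VeffConvention)
        raise ConfigurationError(
            f"unknown excluded-volume convention {convention!r}; valid options: {valid}"
        ) from None
    d3 = diameter_nm**3
    if convention is VeffConvention.sphere_diameter:
        return math.pi / 6.0 * d3
    if convention is VeffConvention.sphere_radius:
        return 4.0 * math.pi / 3.0 * d3
    return d3


def grafting_spacing(density_per_um2: float) -> float:
    """Mean spacing (nm) between grafting sites on a square lattice, n^(-1/2)."""
    if not (density_per_um2 > 0):
        raise DomainError(f"grafting density must be positive, got {density_per_um2}")
    return 1e3 / math.sqrt(density_per_um2)


def debye_length(buffer: BufferSpec) -> float:
    """Debye screening length κ⁻¹ (nm) of a symmetric 1:1 electrolyte.

    κ⁻¹ = sqrt(εr·ε0·kB·T / (2·NA·e²·I)) with I the ionic strength in mol/m³.
    ≈0.78 nm at 150 mM and 298 K (commonly rounded to 0.7 nm).
    """
    ionic_m3 = buffer.ionic_strength_M * 1e3
    kappa_inv_m = math.sqrt(
        buffer.relative_permittivity * EPS0 * KB * buffer.temperature_K
        / (2.0 * NA * E_CHARGE**2 * ionic_m3)
    )
    return kappa_inv_m * 1e9


def surface_density_from_copies(copies_per_cell: float, area_um2: float) -> float:
    """Surface number density (per µm²) from a copy number and a cell area."""
    if copies_per_cell < 0:
        raise DomainError(f"copy number must be nonnegative, got {copies_per_cell}")
    if not (area_um2 > 0):
        raise DomainError(f"surface area must be positive, got {area_um2}")
    return copies_per_cell / area_um2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _adg_brush_height_nm(crowder: CrowderSpec) -> float:
    """Alexander–de Gennes brush height h = N·σ·(n·σ²)^(1/3), in nm."""
    sigma = crowder.bead_diameter_nm
    n_per_nm2 = crowder.grafting_density_per_um2 / 1e6
    reduced = n_per_nm2 * sigma**2
    return crowder.beads_per_chain * sigma * reduced ** (1.0 / 3.0)


def _spherical_cap_volume(radius: float, cap_height: float) -> float:
    """Volume of a spherical cap of height ``cap_height`` cut from a sphere."""
    h = min(max(cap_height, 0.0), 2.0 * radius)
    return math.pi * h * h * (3.0 * radius - h) / 3.0


def brush_insertion_penalty(sensor: SensorSpec, crowder: CrowderSpec) -> CrowdingEnergy:
    """Scaling-theory estimate of the steric penalty for a probe at contact.

    The brush is an Alexander–de Gennes layer of height h_b = N·σ·(n·σ²)^(1/3)
    holding a monomer volume fraction φ = N·σ³·n / h_b = (n·σ²)^(2/3) at
    semidilute osmotic pressure Π_b = (kBT/σ³)·φ^(9/4).  A probe of diameter
    σs whose centre sits at contact height z = σs/2 pays

        ΔU = Π_b · V_overlap,

    with V_overlap the spherical-cap volume of the probe below z = h_b.  The
    result is nonnegative, vanishes on a bare surface, and is monotone
    nondecreasing in grafting density, chain length, bead size, and probe size.
    """
    n_per_nm2 = crowder.grafting_density_per_um2 / 1e6
    if n_per_nm2 == 0:
        return CrowdingEnergy(kd_ratio=1.0, delta_u_kBT=0.0, se_kBT=0.0)
    sigma = crowder.bead_diameter_nm
    h_b = _adg_brush_height_nm(crowder)
    phi = (n_per_nm2 * sigma**2) ** (2.0 / 3.0)
    pressure_kBT_nm3 = phi ** (9.0 / 4.0) / sigma**3
    radius = sensor.diameter_nm / 2.0
    v_overlap = _spherical_cap_volume(radius, h_b)  # probe spans z in [0, σs]
    delta_u = pressure_kBT_nm3 * v_overlap
    return CrowdingEnergy(kd_ratio=math.exp(delta_u), delta_u_kBT=delta_u, se_kBT=0.0)


def effective_antibody_kd(model: AntibodyBindingModel) -> float:
    """Effective dissociation constant of a bivalent antibody (molar).

    Single-parameter avidity correction K_eff = KD1 / (1 + ρ/K2_2D): the
    second arm crosslinks neighbouring antigens once their surface density ρ
    approaches the 2D scale K2_2D, pulling K_eff below the monovalent KD1.
    In the sparse-antigen limit (ρ → 0) the antibody behaves monovalently and
    K_eff → KD1, which is what makes sparse-anchor crowding measurements
    insensitive to the exact anchor density.
    """
    return model.kd1_molar / (1.0 + model.antigen_density_per_um2 / model.k2_2d_per_um2)
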