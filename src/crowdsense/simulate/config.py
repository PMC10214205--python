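"""Simulation configuration for grafted bead-spring brushes.

The model is a Kremer–Grest chain: beads of diameter σ joined by FENE
springs, repelling through a WCA potential, grafted by their first bead to a
flat non-deforming wall at z = 0.  Anchors stay in the z = σ/2 plane but
diffuse laterally (surface proteins are mobile in the membrane).  Charged
brushes add a screened-Coulomb (Yukawa) pair repulsion.

Internally everything runs in reduced units: σ = 1, kBT = 1, friction γ = 1,
so the bead diffusion time τ = σ²γ/kBT is the unit of time.  The public
configuration speaks nm; ``bead_diameter_nm`` sets the length conversion.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import pydantic
from pydantic import BaseModel, ConfigDict

from ..errors import ConfigurationError

#: Euler–Maruyama stability bound on the reduced timestep (fraction of τ).
MAX_TIMESTEP = 1e-4


class YukawaConfig(BaseModel):
    """Screened-Coulomb repulsion U(r) = A·(σ/r)·exp(−κ(r−σ)) between beads."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    amplitude_kBT: float = 2.0
    debye_length_nm: float = 1.0
    cutoff_nm: Optional[float] = None  # default: where U drops below 1e-3 kBT

    @pydantic.field_validator("debye_length_nm")
    @classmethod
    def _positive_debye(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"debye_length_nm must be positive, got {v}")
        return v


class SimulationConfig(BaseModel):
    """Full description of one brush simulation.

    ``grafting_density_per_um2`` is optional redundancy: when given, the box
    and chain count must reproduce it to within one chain.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    box_xy_nm: Tuple[float, float]
    n_chains: int
    beads_per_chain: int
    bead_diameter_nm: float = 4.0
    grafting_density_per_um2: Optional[float] = None
    fene_k: float = 30.0            # kBT/σ²
    fene_r0: float = 1.5            # σ
    wca_epsilon_kBT: float = 1.0
    bending_stiffness_kBT: float = 0.0
    yukawa: Optional[YukawaConfig] = None
    timestep: float = MAX_TIMESTEP  # reduced units of τ
    friction: float = 1.0
    temperature_K: float = 298.0
    seed: int = 0
    tethered: bool = True
    anchor_mobile: bool = True
    wall: bool = True
    ideal: bool = False             # disable pair forces (oracle/testing mode)
    slab_height_nm: Optional[float] = None  # reflective ceiling for ideal gases

    @pydantic.model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        bx, by = self.box_xy_nm
        if bx <= 0 or by <= 0:
            raise ValueError(f"box dimensions must be positive, got {self.box_xy_nm}")
        if self.n_chains < 0:
            raise ValueError(f"n_chains must be nonnegative, got {self.n_chains}")
        if self.beads_per_chain < 1:
            raise ValueError(f"beads_per_chain must be >= 1, got {self.beads_per_chain}")
        if self.bead_diameter_nm <= 0:
            raise ValueError(f"bead_diameter_nm must be positive, got {self.bead_diameter_nm}")
        if self.fene_r0 <= 1.0:
            raise ValueError(f"fene_r0 must exceed 1 σ, got {self.fene_r0}")
        if not (0 < self.timestep <= MAX_TIMESTEP):
            raise ValueError(
                f"timestep must be in (0, {MAX_TIMESTEP}] τ for stability, got {self.timestep}"
            )
        if self.friction <= 0:
            raise ValueError(f"friction must be positive, got {self.friction}")
        return self

    @property
    def sigma_nm(self) -> float:
        return self.bead_diameter_nm

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def box_area_um2(self) -> float:
        return self.box_xy_nm[0] * self.box_xy_nm[1] * 1e-6

    @property
    def actual_density_per_um2(self) -> float:
        return self.n_chains / self.box_area_um2

    def check_density(self) -> None:
        """Verify box/chain count against the requested grafting density."""
        if self.grafting_density_per_um2 is None:
            return
        expected = self.grafting_density_per_um2 * self.box_area_um2
        if abs(expected - self.n_chains) > 1.0:
            raise ConfigurationError(
                f"n_chains={self.n_chains} is inconsistent with "
                f"{self.grafting_density_per_um2}/µm² over a "
                f"{self.box_xy_nm[0]}×{self.box_xy_nm[1]} nm² box "
                f"(expected {expected:.1f} chains, tolerance one chain)"
            )

    def yukawa_reduced(self) -> Tuple[float, float, float]:
        """(amplitude, κσ, cutoff²) in reduced units; zeros when disabled."""
        if self.yukawa is None:
            return 0.0, 0.0, 0.0
        a = self.yukawa.amplitude_kBT
        kappa = self.sigma_nm / self.yukawa.debye_length_nm
        if self.yukawa.cutoff_nm is not None:
            rc = self.yukawa.cutoff_nm / self.sigma_nm
        else:
            # smallest r with |U(r)| < 1e-3 kBT
            rc = 1.0
            while abs(a / rc * math.exp(-kappa * (rc - 1.0))) > 1e-3 and rc < 20.0:
                rc += 0.05
        return a, kappa, rc * rc


def chains_for_density(box_xy_nm: Tuple[float, float], density_per_um2: float) -> int:
    """Number of chains reproducing ``density_per_um2`` in the given box."""
    if density_per_um2 < 0:
        raise ConfigurationError(f"density must be nonnegative, got {density_per_um2}")
    return int(round(density_per_um2 * box_xy_nm[0] * box_xy_nm[1] * 1e-6))
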