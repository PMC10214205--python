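"""Widom test-particle insertion free energies and affinity ratios.

The steric free energy of a probe at height z above the wall is estimated by
inserting ghost probes at seeded uniform xy positions into equilibrated brush
frames:

    U(z) = −kBT · ln ⟨exp(−βΔE)⟩.

For a hard-sphere probe the Boltzmann average reduces to the non-overlap
fraction, with a binomial/delta-method standard error per bin.  The bare
surface well depth cancels in ΔU = U_crowded − U_bare, so profiles here are
steric-only and the affinity ratio is read at the binding height z_b = σs/2
(probe touching the wall) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ..errors import DomainError, UsageError
from ..theory import CrowdingEnergy
from .kernels import widom_hard_count, widom_soft_weights

__all__ = ["FreeEnergyProfile", "widom_insertion_profile", "kd_ratio_from_profiles"]


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Steric insertion free energy U(z) of a probe above a surface.

    Bins where every insertion overlapped carry ``inf`` in both ``u_kBT`` and
    ``se_kBT`` — unreliable, flagged, never silently dropped.
    """

    z_nm: np.ndarray
    u_kBT: np.ndarray
    se_kBT: np.ndarray
    attempts: np.ndarray
    probe_diameter_nm: float

    def u_at(self, z_nm: float) -> Tuple[float, float]:
        """Linearly interpolated (U, SE) at ``z_nm``; errors outside the grid."""
        zs = self.z_nm
        if not (zs.min() - 1e-9 <= z_nm <= zs.max() + 1e-9):
            raise UsageError(
                f"height {z_nm} nm is outside the profile grid "
                f"[{zs.min()}, {zs.max()}] nm"
            )
        u = float(np.interp(z_nm, zs, self.u_kBT))
        se = float(np.interp(z_nm, zs, self.se_kBT))
        return u, se


def widom_insertion_profile(
    frames: np.ndarray,
    box_xy_nm: Tuple[float, float],
    probe_diameter_nm: float,
    z_grid_nm: Sequence[float],
    n_insertions: int = 100_000,
    seed: int = 0,
    bead_diameter_nm: float = 4.0,
    mode: str = "hard",
) -> FreeEnergyProfile:
    """Insertion free-energy profile of a spherical probe over brush frames.

    ``frames`` has shape (n_frames, n_beads, 3) in nm (n_beads may be 0 for a
    bare wall).  ``n_insertions`` counts total trial insertions per z value,
    spread evenly over frames.  ``mode`` is ``"hard"`` (hard-sphere overlap)
    or ``"soft"`` (WCA probe–bead energy with ε = 1 kBT).
    """
    if probe_diameter_nm <= 0:
        raise DomainError(f"probe diameter must be positive, got {probe_diameter_nm}")
    if n_insertions < 1:
        raise DomainError(f"n_insertions must be >= 1, got {n_insertions}")
    frames = np.ascontiguousarray(np.asarray(frames, dtype=np.float64))
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise UsageError("at least one frame of shape (n_beads, 3) is required")
    if mode not in ("hard", "soft"):
        raise UsageError(f"mode must be 'hard' or 'soft', got {mode!r}")

    n_frames = frames.shape[0]
    per_frame = max(1, int(math.ceil(n_insertions / n_frames)))
    z_grid = np.asarray(z_grid_nm, dtype=float)
    u = np.empty_like(z_grid)
    se = np.empty_like(z_grid)
    attempts = np.empty_like(z_grid, dtype=np.int64)
    contact = 0.5 * (probe_diameter_nm + bead_diameter_nm)
    wall_contact = 0.5 * probe_diameter_nm
    seeds = np.random.SeedSequence(seed).generate_state(len(z_grid)) & 0x7FFFFFFF

    for k, z in enumerate(z_grid):
        if z < wall_contact - 1e-9:
            # probe overlaps the hard wall regardless of the brush
            u[k], se[k], attempts[k] = math.inf, math.inf, 0
            continue
        if frames.shape[1] == 0:
            u[k], se[k] = 0.0, 0.0
            attempts[k] = per_frame * n_frames
            continue
        if mode == "hard":
            ok, total = widom_hard_count(
                frames, box_xy_nm[0], box_xy_nm[1], z, contact * contact,
                per_frame, int(seeds[k]),
            )
            attempts[k] = total
            if ok == 0:
                u[k], se[k] = math.inf, math.inf
            else:
                p = ok / total
                u[k] = -math.log(p)
                se[k] = math.sqrt((1.0 - p) / (p * total))
        else:
            wsum, w2sum, total = widom_soft_weights(
                frames, box_xy_nm[0], box_xy_nm[1], z, contact, 1.0,
                per_frame, int(seeds[k]),
            )
            attempts[k] = total
            if wsum == 0.0:
                u[k], se[k] = math.inf, math.inf
            else:
                mean = wsum / total
                var = max(w2sum / total - mean * mean, 0.0)
                u[k] = -math.log(mean)
                se[k] = math.sqrt(var / total) / mean
    return FreeEnergyProfile(
        z_nm=z_grid, u_kBT=u, se_kBT=se, attempts=attempts,
        probe_diameter_nm=probe_diameter_nm,
    )


def kd_ratio_from_profiles(
    crowded: FreeEnergyProfile,
    bare: FreeEnergyProfile,
    binding_height_nm: Optional[float] = None,
) -> CrowdingEnergy:
    """Affinity ratio KD/KD0 = exp(ΔU) read at the binding height.

    ΔU = U_crowded(z_b) − U_bare(z_b); the default z_b = σs/2 puts the probe
    in contact with the wall.  Standard errors combine in quadrature.
    """
    if not math.isclose(crowded.probe_diameter_nm, bare.probe_diameter_nm):
        raise UsageError(
            f"profiles describe different probes "
            f"({crowded.probe_diameter_nm} vs {bare.probe_diameter_nm} nm)"
        )
    z_b = binding_height_nm if binding_height_nm is not None else crowded.probe_diameter_nm / 2.0
    u_c, se_c = crowded.u_at(z_b)
    u_0, se_0 = bare.u_at(z_b)
    delta_u = u_c - u_0
    se = math.hypot(se_c, se_0)
    return CrowdingEnergy(kd_ratio=math.exp(delta_u), delta_u_kBT=delta_u, se_kBT=se)
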