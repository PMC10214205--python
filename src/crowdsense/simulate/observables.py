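"""Density profiles and brush heights from sampled frames."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..errors import DomainError, UsageError

__all__ = ["DensityProfile", "BrushHeightResult", "density_profile", "brush_height"]


@dataclass(frozen=True)
class DensityProfile:
    """Bead number density ρ(z), per nm³, averaged over frames.

    ``frame_mean_heights`` keeps the per-frame first moments so the brush
    height carries a frame-to-frame standard error.
    """

    z_nm: np.ndarray
    rho_per_nm3: np.ndarray
    bin_width_nm: float
    box_area_nm2: float
    n_frames: int
    frame_mean_heights: np.ndarray

    def total_beads(self) -> float:
        """∑ ρ·Δz·A — mean bead count per frame (conservation check)."""
        return float(self.rho_per_nm3.sum() * self.bin_width_nm * self.box_area_nm2)


@dataclass(frozen=True)
class BrushHeightResult:
    """Mean brush height ⟨h⟩ = ∫z·ρ dz / ∫ρ dz, optionally normalized by h0."""

    mean_height_nm: float
    se_nm: float
    h0_nm: Optional[float] = None

    @property
    def normalized(self) -> Optional[float]:
        return None if self.h0_nm is None else self.mean_height_nm / self.h0_nm


def density_profile(
    frames: np.ndarray,
    box_xy_nm: Tuple[float, float],
    bin_width_nm: float = 0.5,
    z_max_nm: Optional[float] = None,
) -> DensityProfile:
    """Histogram bead heights into a z density profile.

    Conservation holds exactly: the profile integrates to the mean bead count
    per frame over the box area.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise UsageError("at least one frame of shape (n_beads, 3) is required")
    if bin_width_nm <= 0:
        raise DomainError(f"bin width must be positive, got {bin_width_nm}")
    z = frames[..., 2]
    if z_max_nm is None:
        z_max_nm = float(z.max()) + bin_width_nm if z.size else bin_width_nm
    n_bins = max(1, int(np.ceil(z_max_nm / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(z.ravel(), bins=edges)
    area = box_xy_nm[0] * box_xy_nm[1]
    n_frames = frames.shape[0]
    rho = counts / (n_frames * area * bin_width_nm)
    with np.errstate(invalid="ignore"):
        frame_means = z.mean(axis=1) if z.shape[1] else np.full(n_frames, np.nan)
    return DensityProfile(
        z_nm=0.5 * (edges[:-1] + edges[1:]),
        rho_per_nm3=rho,
        bin_width_nm=bin_width_nm,
        box_area_nm2=area,
        n_frames=n_frames,
        frame_mean_heights=frame_means,
    )


def brush_height(profile: DensityProfile, h0_nm: Optional[float] = None) -> BrushHeightResult:
    """First moment of the density profile, with a frame-level standard error."""
    mass = profile.rho_per_nm3.sum()
    if mass <= 0:
        raise DomainError("density profile has zero mass; no beads to average")
    mean = float((profile.z_nm * profile.rho_per_nm3).sum() / mass)
    fm = profile.frame_mean_heights
    fm = fm[np.isfinite(fm)]
    se = float(fm.std(ddof=1) / np.sqrt(len(fm))) if len(fm) > 1 else 0.0
    return BrushHeightResult(mean_height_nm=mean, se_nm=se, h0_nm=h0_nm)
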