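"""Offset-calibrated mean surface-height analysis (the arithmetic layer of
cell surface optical profilometry).

A fluorophore's apparent height above the membrane mixes the true label
height with chromatic aberration and other optical offsets.  A baseline
calibration on a membrane-proximal sensor pair measures the mean offset
⟨h_offset⟩, and the reported surface height is

    ⟨h⟩ = mean(h_measured) − ⟨h_offset⟩,

with the two standard errors combined in quadrature (independent noise
sources).  Cells flagged at acquisition (nonspherical, tubulated, budding)
are excluded before any averaging and counted in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "QC_FLAGS",
    "OffsetCalibration",
    "MeanHeight",
    "PercentChange",
    "qc_pass",
    "calibrate_offset",
    "mean_height",
    "relative_height_change",
]

QC_FLAGS = frozenset({"nonspherical", "tubule", "bud", "none"})


def _parse_flags(value) -> frozenset:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    if isinstance(value, (set, frozenset, list, tuple)):
        flags = frozenset(map(str, value))
    else:
        flags = frozenset(p.strip() for p in str(value).split(";") if p.strip())
    unknown = flags - QC_FLAGS
    if unknown:
        raise DataError(f"unknown QC flag(s) {sorted(unknown)}; valid: {sorted(QC_FLAGS)}")
    return flags - {"none"}


def qc_pass(measurements: pd.DataFrame) -> pd.Series:
    """Boolean mask of cells with no disqualifying QC flag."""
    if "qc_flags" not in measurements.columns:
        return pd.Series(True, index=measurements.index)
    return measurements["qc_flags"].map(lambda v: len(_parse_flags(v)) == 0)


@dataclass(frozen=True)
class OffsetCalibration:
    """Population-mean optical offset ⟨h_offset⟩ from reference cells."""

    mean_offset_nm: float
    se_nm: float  # NaN for a single-measurement calibration (flagged)
    n_reference: int

    @property
    def single_measurement(self) -> bool:
        return self.n_reference == 1


@dataclass(frozen=True)
class MeanHeight:
    """Offset-corrected mean label height."""

    mean_nm: float
    se_nm: float
    n_cells: int
    n_excluded: int


@dataclass(frozen=True)
class PercentChange:
    """Percent reduction in height between two conditions."""

    percent: float
    se: float


def _validated_heights(measurements: pd.DataFrame, context: str) -> np.ndarray:
    if measurements is None or len(measurements) == 0:
        raise DataError(f"{context}: no measurements supplied")
    if "h_measured_nm" not in measurements.columns:
        raise DataError(f"{context}: column 'h_measured_nm' is missing")
    keep = qc_pass(measurements)
    if not keep.any():
        flags = sorted(
            {f for v in measurements.get("qc_flags", []) for f in _parse_flags(v)}
        )
        raise DataError(
            f"{context}: every cell is QC-flagged ({', '.join(flags) or 'unknown flags'})"
        )
    h = measurements.loc[keep, "h_measured_nm"].to_numpy(float)
    if not np.all(np.isfinite(h)):
        raise DataError(f"{context}: heights must be finite")
    return h


def calibrate_offset(reference: pd.DataFrame) -> OffsetCalibration:
    """Mean and SE of the optical offset from QC-passing reference cells."""
    h = _validated_heights(reference, "offset calibration")
    se = float(h.std(ddof=1) / math.sqrt(len(h))) if len(h) > 1 else math.nan
    return OffsetCalibration(mean_offset_nm=float(h.mean()), se_nm=se, n_reference=len(h))


def mean_height(
    measurements: pd.DataFrame,
    calibration: Optional[OffsetCalibration] = None,
) -> MeanHeight:
    """Offset-corrected mean height ⟨h⟩ = mean(h_measured) − ⟨h_offset⟩."""
    h = _validated_heights(measurements, "height measurement")
    n_excluded = len(measurements) - len(h)
    sample_se = float(h.std(ddof=1) / math.sqrt(len(h))) if len(h) > 1 else 0.0
    offset = calibration.mean_offset_nm if calibration else 0.0
    cal_se = 0.0
    if calibration and math.isfinite(calibration.se_nm):
        cal_se = calibration.se_nm
    return MeanHeight(
        mean_nm=float(h.mean()) - offset,
        se_nm=math.hypot(sample_se, cal_se),
        n_cells=len(h),
        n_excluded=n_excluded,
    )


def relative_height_change(untreated: MeanHeight, treated: MeanHeight) -> PercentChange:
    """Percent height reduction 100·(h_u − h_t)/h_u with propagated SE."""
    if untreated.mean_nm <= 0:
        raise DomainError(
            f"untreated mean height must be positive, got {untreated.mean_nm}"
        )
    hu, ht = untreated.mean_nm, treated.mean_nm
    pct = 100.0 * (hu - ht) / hu
    se = 100.0 * math.hypot(ht / hu**2 * untreated.se_nm, treated.se_nm / hu)
    return PercentChange(percent=pct, se=se)
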