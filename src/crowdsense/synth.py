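"""Seeded synthetic-data generators.

These generators stand in for every wet-lab input: flow-cytometry event
tables with realistic cell-to-cell dispersion, single-cell crowding
populations with optional expression dependence, and offset-corrupted
surface-height tables.  Each emulates the statistical structure the analysis
layers assume — lognormal cell-size (Cmax) variation, Langmuir binding with a
specified true KD and crowding factor, multiplicative detection noise, and
additive background — and every draw is bit-reproducible under a fixed seed.

Default study conditions: Cmax lognormal CV 25%, detection CV 10%, additive
background SD equal to 1% of the median noiseless signal, and a bulk
concentration grid {0.05, 0.1, 0.25, 0.5, 1, 2} nM spanning well below a
10 nM reference KD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .theory import CrowderSpec, SensorSpec

__all__ = [
    "DEFAULT_CONC_GRID_NM",
    "NoiseModel",
    "ScenarioPreset",
    "gen_isotherm_events",
    "gen_population",
    "gen_csop_dataset",
    "scenario",
    "available_scenarios",
]

DEFAULT_CONC_GRID_NM: Tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0)

#: arbitrary intensity scale of the per-cell saturation signal
CMAX_SCALE = 1000.0
#: anchor channel gain relative to Cmax; 1.0 means the anchor channel reports
#: the saturation signal in probe-equivalent units, so probe/anchor ≈ θ
ANCHOR_GAIN = 1.0


@dataclass(frozen=True)
class NoiseModel:
    """Event-level noise: cell-size spread, detection noise, background.

    ``cmax_lognormal_cv`` — CV of the lognormal per-cell saturation signal
    (cell size / anchor density heterogeneity).  ``detection_cv`` —
    multiplicative (lognormal) noise applied independently per channel.
    ``background_sd`` — additive Gaussian background in probe-channel units;
    ``None`` means 1% of the median noiseless probe signal.
    """

    cmax_lognormal_cv: float = 0.25
    detection_cv: float = 0.10
    background_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cmax_lognormal_cv < 0:
            raise DomainError(f"cmax CV must be nonnegative, got {self.cmax_lognormal_cv}")
        if self.detection_cv < 0:
            raise DomainError(f"detection CV must be nonnegative, got {self.detection_cv}")
        if self.background_sd is not None and self.background_sd < 0:
            raise DomainError(f"background SD must be nonnegative, got {self.background_sd}")

    def quiet(self) -> "NoiseModel":
        """The noiseless limit (useful for exactness tests)."""
        return replace(self, cmax_lognormal_cv=0.0, detection_cv=0.0, background_sd=0.0)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with arithmetic mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def _background(rng: np.random.Generator, noise: NoiseModel, signal: np.ndarray) -> np.ndarray:
    sd = noise.background_sd
    if sd is None:
        med = float(np.median(signal))
        sd = 0.01 * med if med > 0 else 0.0
    if sd == 0:
        return np.zeros_like(signal)
    return rng.normal(0.0, sd, size=len(signal))


def _sample_events(
    rng: np.random.Generator,
    sample_id: str,
    kd_nM: np.ndarray,
    conc_nM: float,
    noise: NoiseModel,
    expression: Optional[np.ndarray] = None,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """One sample at one bulk concentration; ``kd_nM`` is per-cell."""
    n = len(kd_nM)
    cmax = CMAX_SCALE * _lognormal_unit_mean(rng, noise.cmax_lognormal_cv, n)
    bound = cmax * conc_nM / (conc_nM + kd_nM)  # physical: never exceeds Cmax
    probe = bound * _lognormal_unit_mean(rng, noise.detection_cv, n)
    probe = np.maximum(probe + _background(rng, noise, probe), 0.0)
    anchor = ANCHOR_GAIN * cmax * _lognormal_unit_mean(rng, noise.detection_cv, n)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": np.arange(n),
            "bulk_conc_nM": conc_nM,
            "anchor_fitc": anchor,
            "probe_signal": probe,
            "expression": expression if expression is not None else np.nan,
            "treatment": treatment if treatment is not None else pd.NA,
        }
    )


def gen_isotherm_events(
    kd0_nM: float = 10.0,
    kd_ratio: float = 1.55,
    concs_nM: Sequence[float] = DEFAULT_CONC_GRID_NM,
    n_events_per_conc: int = 20_000,
    noise: NoiseModel = NoiseModel(),
    reference_name: str = "bare_bead",
    crowded_name: str = "crowded",
) -> pd.DataFrame:
    """Two-sample event table: a bare reference (KD0) and a crowded surface
    (KD = KD0·kd_ratio) across a bulk-concentration grid.

    Emulates the bead isotherm experiment: every cell carries a lognormal
    Cmax, the anchor channel reports Cmax, and the probe channel reports
    Langmuir-bound sensor with detection noise and background.
    """
    if kd0_nM <= 0 or kd_ratio <= 0:
        raise DomainError(f"KD0 and kd_ratio must be positive, got {kd0_nM}, {kd_ratio}")
    if len(concs_nM) == 0:
        raise DomainError("concentration grid is empty")
    if min(concs_nM) < 0:
        raise DomainError(f"concentrations must be nonnegative, got {min(concs_nM)}")
    if n_events_per_conc < 1:
        raise DomainError(f"n_events_per_conc must be >= 1, got {n_events_per_conc}")
    rng = np.random.default_rng(noise.seed)
    parts = []
    for name, kd in ((reference_name, kd0_nM), (crowded_name, kd0_nM * kd_ratio)):
        for c in sorted(concs_nM):
            parts.append(
                _sample_events(rng, name, np.full(n_events_per_conc, kd), c, noise)
            )
    return pd.concat(parts, ignore_index=True)


def gen_population(
    mean_kd_ratio: float = 22.0,
    cv: float = 0.3,
    n_cells: int = 5_000,
    fixed_conc_nM: float = 0.1,
    kd0_nM: float = 1.0,
    expression_model: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    expression_decades: float = 2.5,
    noise: NoiseModel = NoiseModel(),
    reference_name: str = "bare_bead",
    population_name: str = "cells",
    n_reference: Optional[int] = None,
) -> pd.DataFrame:
    """Single-cell population with lognormal per-cell crowding.

    Per-cell affinity ratios are lognormal with geometric mean
    ``mean_kd_ratio`` and coefficient of variation ``cv``.  When an
    ``expression_model`` (a vectorized map expression → crowding energy ΔU in
    kBT) is supplied, an expression channel spanning ``expression_decades``
    decades is drawn and the systematic part of each cell's crowding becomes
    exp(ΔU(expression)), with the lognormal heterogeneity multiplying on top.
    A bare reference sample at KD0 is emitted alongside.
    """
    if cv < 0:
        raise DomainError(f"cv must be nonnegative, got {cv}")
    if mean_kd_ratio <= 0 or kd0_nM <= 0:
        raise DomainError("mean_kd_ratio and kd0_nM must be positive")
    rng = np.random.default_rng(noise.seed)
    expression = None
    if expression_model is not None:
        log_sd = expression_decades / 4.0  # ±2 SD spans the requested decades
        expression = 10.0 ** rng.normal(2.0, log_sd, size=n_cells)
        try:
            base = np.exp(np.asarray(expression_model(expression), dtype=float))
        except Exception as exc:
            raise ConfigurationError(f"expression model is not usable: {exc}") from exc
        if base.shape != (n_cells,):
            raise ConfigurationError(
                "expression model must map an (n,) expression array to (n,) ΔU values"
            )
        ratios = base * _lognormal_unit_mean(rng, cv, n_cells)
    else:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        ratios = rng.lognormal(math.log(mean_kd_ratio), sigma, size=n_cells)
    pop = _sample_events(
        rng, population_name, kd0_nM * ratios, fixed_conc_nM, noise, expression=expression
    )
    ref = _sample_events(
        rng, reference_name,
        np.full(n_reference or n_cells, kd0_nM), fixed_conc_nM, noise,
    )
    return pd.concat([ref, pop], ignore_index=True)


def gen_csop_dataset(
    true_height_nm: float = 10.0,
    offset_nm: float = 12.0,
    noise_sd_nm: float = 2.0,
    n_cells: int = 120,
    defect_fraction: float = 0.0,
    n_reference: int = 100,
    label: str = "N-term",
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Surface-height measurements plus a matching offset calibration table.

    Measured heights are true height + offset + Gaussian noise; a
    ``defect_fraction`` of cells receives a disqualifying QC flag.  Returns
    (measurements, calibration) frames in the CSV layout the height module
    reads.
    """
    if not (0.0 <= defect_fraction <= 1.0):
        raise DomainError(f"defect_fraction must lie in [0, 1], got {defect_fraction}")
    rng = np.random.default_rng(seed)
    measured = true_height_nm + offset_nm + rng.normal(0.0, noise_sd_nm, n_cells)
    defect = rng.random(n_cells) < defect_fraction
    flags = np.where(
        defect, rng.choice(["nonspherical", "tubule", "bud"], size=n_cells), "none"
    )
    measurements = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "h_measured_nm": measured,
            "label": label,
            "qc_flags": flags,
        }
    )
    calibration = pd.DataFrame(
        {
            "cell_id": np.arange(n_reference),
            "h_measured_nm": offset_nm + rng.normal(0.0, noise_sd_nm, n_reference),
            "label": "calibration",
            "qc_flags": "none",
        }
    )
    return measurements, calibration


@dataclass(frozen=True)
class ScenarioPreset:
    """A named experimental condition: surface, sensor, and true effect size."""

    name: str
    surface: CrowderSpec
    sensor: SensorSpec
    true_kd_ratio: float
    notes: str = ""


_DEX40K = SensorSpec("dex40k", diameter_nm=10.0)
_IGG = SensorSpec("anti_biotin_igg", diameter_nm=10.0)


def _fib(n: int, density: float = 10_000.0) -> CrowderSpec:
    return CrowderSpec(
        name=f"Fib{n}L", beads_per_chain=n, bead_diameter_nm=4.0,
        grafting_density_per_um2=density,
    )


_SCENARIOS = {
    "bare_bead": ScenarioPreset(
        "bare_bead",
        CrowderSpec("none", 1, 4.0, 0.0),
        _DEX40K, 1.0, "bare lipid-coated bead; the KD0 reference",
    ),
    "peg3k_1pct": ScenarioPreset(
        "peg3k_1pct",
        CrowderSpec("PEG3k", 5, 1.2, 15_000.0),
        _DEX40K, 1.55,
        "1% (mol/mol) PEG3k, ~15,000/µm²; dextran-40k KD rises 55%",
    ),
    "fib1L": ScenarioPreset("fib1L", _fib(1), _DEX40K, 1.2,
                            "single Fibcon domain (~4 nm); ~20% KD increase"),
    "fib3L": ScenarioPreset("fib3L", _fib(3), _DEX40K, 2.0,
                            "three Fibcon domains; KD increase >2x (lower bound)"),
    "fib5L": ScenarioPreset("fib5L", _fib(5), _DEX40K, 2.0,
                            "five Fibcon domains; KD increase >2x (lower bound)"),
    "gypa": ScenarioPreset(
        "gypa",
        CrowderSpec("GYPA", 5, 4.0, 2_000.0, charge_per_bead_e=-6.0),
        _DEX40K, 2.0, "sialylated Glycophorin A on beads; 2x KD increase",
    ),
    "gypa_sialidase": ScenarioPreset(
        "gypa_sialidase",
        CrowderSpec("GYPA-asialo", 5, 4.0, 2_000.0),
        _DEX40K, 1.2, "sialidase-treated GYPA; KD 40% below the untreated surface",
    ),
    "rbc": ScenarioPreset(
        "rbc",
        CrowderSpec("rbc_surface", 5, 4.0, 8_000.0, charge_per_bead_e=-3.0),
        _DEX40K, 2.5, "red blood cell vs ProK-treated reference",
    ),
    "rbc_sialidase": ScenarioPreset(
        "rbc_sialidase",
        CrowderSpec("rbc_asialo", 5, 4.0, 8_000.0),
        _DEX40K, 1.5, "sialidase-treated RBC; KD 40% below untreated",
    ),
    "skbr_like": ScenarioPreset(
        "skbr_like",
        CrowderSpec("tumor_glycocalyx", 10, 4.0, 15_000.0, charge_per_bead_e=-6.0),
        _IGG, 22.0, "malignant breast epithelial surface; KD/KD0 ≈ 22",
    ),
    "mcf10a_like": ScenarioPreset(
        "mcf10a_like",
        CrowderSpec("normal_glycocalyx", 8, 4.0, 10_000.0, charge_per_bead_e=-4.0),
        _IGG, 11.0, "non-malignant breast epithelial surface; half the SKBR crowding",
    ),
}


def available_scenarios() -> Tuple[str, ...]:
    return tuple(sorted(_SCENARIOS))


def scenario(name: str) -> ScenarioPreset:
    """Look up a named experimental scenario preset."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        ) from None
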