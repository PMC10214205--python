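"""Flow-cytometry isotherm pipeline.

Per-event tables (one row per cell per bulk sensor concentration) are turned
into Langmuir binding isotherms, dissociation-constant ratios KD/KD0,
crowding energies, single-cell crowding distributions, expression-binned
curves, and replicate-level group comparisons.

The central trick is per-event normalization: dividing the sensor/antibody
channel by the anchor (FITC) channel cancels cell-size and anchor-density
variation because both channels scale with the per-cell saturation
concentration Cmax.  Intensity units are arbitrary throughout — only ratios
of low-concentration isotherm slopes are interpreted, and any detector gain
cancels there.

Orientation note: the low-concentration slope of θ(C) ≈ C/KD is 1/KD, so the
ratio of the *reference* slope over the *sample* slope equals KD/KD0 and
exceeds 1 on crowded surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DataError, DomainError, EstimationError, UsageError
from .theory import CrowdingEnergy, crowding_energy_from_kd_ratio

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "GateReport",
    "BindingIsotherm",
    "KdRatioResult",
    "LangmuirFit",
    "PopulationCrowding",
    "GroupComparison",
    "validate_events",
    "normalize_events",
    "build_isotherm",
    "low_conc_slope",
    "kd_ratio_from_slopes",
    "fit_langmuir",
    "langmuir",
    "single_cell_crowding",
    "bin_by_expression",
    "compare_groups",
    "significance_band",
]

REQUIRED_COLUMNS = ("sample_id", "cell_id", "bulk_conc_nM", "anchor_fitc", "probe_signal")
OPTIONAL_COLUMNS = ("expression", "treatment")


def langmuir(conc: np.ndarray, kd: float) -> np.ndarray:
    """Fractional occupancy θ = C/(C+KD) of independent identical sites."""
    conc = np.asarray(conc, dtype=float)
    return conc / (conc + kd)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical event-table schema and fill optional columns."""
    if events is None or len(events) == 0:
        raise DataError("event table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise DataError(f"event table is missing required column(s): {', '.join(missing)}")
    events = events.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in events.columns:
            events[col] = np.nan
    for col in ("bulk_conc_nM", "anchor_fitc", "probe_signal"):
        bad = events.index[~np.isfinite(pd.to_numeric(events[col], errors="coerce"))]
        if len(bad):
            raise DataError(
                f"column {col!r} has non-numeric or missing values at rows "
                f"{list(bad[:5])}{'...' if len(bad) > 5 else ''}"
            )
    if (events["anchor_fitc"] < 0).any() or (events["probe_signal"] < 0).any():
        raise DataError("channel intensities must be nonnegative")
    return events


@dataclass(frozen=True)
class GateReport:
    """Bookkeeping for anchor-channel gating."""

    n_input: int
    n_retained: int
    n_below: int
    n_above: int
    low_threshold: float
    high_threshold: float


def normalize_events(
    events: pd.DataFrame,
    anchor_floor: float = 0.0,
    low_quantile: float = 0.01,
    high_quantile: float = 0.999,
) -> Tuple[pd.DataFrame, GateReport]:
    """Gate on the anchor channel and attach the normalized signal.

    Events below max(``anchor_floor``, the ``low_quantile`` anchor quantile)
    or above the ``high_quantile`` quantile are dropped and counted; the
    retained events gain a ``norm_signal`` = probe/anchor column.
    """
    events = validate_events(events)
    anchor = events["anchor_fitc"].to_numpy(dtype=float)
    lo = max(anchor_floor, float(np.quantile(anchor, low_quantile)))
    hi = float(np.quantile(anchor, high_quantile))
    below = anchor < lo
    above = anchor > hi
    keep = ~(below | above) & (anchor > 0)
    report = GateReport(
        n_input=len(events),
        n_retained=int(keep.sum()),
        n_below=int(below.sum()),
        n_above=int(above.sum()),
        low_threshold=lo,
        high_threshold=hi,
    )
    if report.n_retained == 0:
        raise DataError(
            f"all {report.n_input} events were gated out "
            f"(thresholds [{lo:.4g}, {hi:.4g}]); check the anchor channel"
        )
    out = events.loc[keep].copy()
    out["norm_signal"] = out["probe_signal"].to_numpy(float) / out["anchor_fitc"].to_numpy(float)
    return out, report


@dataclass
class BindingIsotherm:
    """Concentration-grouped mean normalized bound signal for one sample.

    ``theta`` is the group mean of probe/anchor (proportional to the true
    fractional coverage up to one unknown detector gain).  The per-event
    table is retained for bootstrap resampling.
    """

    sample_id: str
    conc_nM: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    n_events: np.ndarray
    events: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        order = np.argsort(self.conc_nM)
        self.conc_nM = np.asarray(self.conc_nM, float)[order]
        self.theta = np.asarray(self.theta, float)[order]
        self.se = np.asarray(self.se, float)[order]
        self.n_events = np.asarray(self.n_events, int)[order]
        if np.any(self.n_events <= 0):
            raise DataError("every isotherm point needs at least one event")
        if np.any(np.diff(self.conc_nM) <= 0):
            raise DataError("concentrations must be strictly increasing")


def build_isotherm(events: pd.DataFrame, sample_id: Optional[str] = None) -> BindingIsotherm:
    """Group normalized events of one sample by bulk concentration."""
    if "norm_signal" not in events.columns:
        raise UsageError("run normalize_events first: 'norm_signal' column missing")
    samples = events["sample_id"].unique()
    if sample_id is None:
        if len(samples) != 1:
            raise UsageError(
                f"event table holds {len(samples)} samples {sorted(map(str, samples))}; "
                "pass sample_id to select one"
            )
        sample_id = samples[0]
    sub = events[events["sample_id"] == sample_id]
    if len(sub) == 0:
        raise UsageError(f"no events for sample {sample_id!r}")
    g = sub.groupby("bulk_conc_nM")["norm_signal"]
    mean = g.mean()
    sd = g.std(ddof=1).fillna(0.0)
    n = g.size()
    return BindingIsotherm(
        sample_id=str(sample_id),
        conc_nM=mean.index.to_numpy(float),
        theta=mean.to_numpy(float),
        se=(sd / np.sqrt(n)).to_numpy(float),
        n_events=n.to_numpy(int),
        events=sub,
    )


def _origin_slope(conc: np.ndarray, theta: np.ndarray) -> float:
    """Weighted origin slope with inverse-variance weights 1/C².

    With multiplicative detection noise the group-mean SD scales with θ̄ ∝ C,
    so weights 1/C² are the statistically efficient choice; conveniently they
    also emphasise the smallest concentrations, where the Langmuir
    linearization θ ≈ C/KD is most accurate.  Algebraically the estimator is
    the mean of the per-point ratios θ̄/C.
    """
    return float(np.mean(theta / conc))


def low_conc_slope(
    isotherm: BindingIsotherm,
    theta_cutoff: float = 0.2,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Low-concentration isotherm slope (≈ 1/KD) with a bootstrap SE.

    Only points with mean coverage below ``theta_cutoff`` enter the fit (the
    linearization bias of θ = C/(C+KD) is < cutoff and shrinks as C → 0).
    The SE comes from resampling events within each concentration group.
    """
    mask = isotherm.theta < theta_cutoff
    if mask.sum() < 2:
        raise EstimationError(
            f"only {int(mask.sum())} isotherm point(s) have mean coverage below "
            f"{theta_cutoff}; use the full Langmuir fit instead"
        )
    conc = isotherm.conc_nM[mask]
    slope = _origin_slope(conc, isotherm.theta[mask])
    se = 0.0
    if n_bootstrap > 0 and isotherm.events is not None:
        rng = np.random.default_rng(seed)
        groups = [
            isotherm.events.loc[
                isotherm.events["bulk_conc_nM"] == c, "norm_signal"
            ].to_numpy(float)
            for c in conc
        ]
        boots = np.empty(n_bootstrap)
        chunk = max(1, min(n_bootstrap, int(2e6 / max(len(g) for g in groups))))
        done = 0
        while done < n_bootstrap:
            m = min(chunk, n_bootstrap - done)
            means = np.empty((m, len(groups)))
            for gi, g in enumerate(groups):
                idx = rng.integers(0, len(g), size=(m, len(g)))
                means[:, gi] = g[idx].mean(axis=1)
            boots[done:done + m] = (means / conc).mean(axis=1)
            done += m
        se = float(boots.std(ddof=1))
    return slope, se


def kd_ratio_from_slopes(
    reference_slope: float,
    sample_slope: float,
    reference_se: float = 0.0,
    sample_se: float = 0.0,
    reference_sample: str = "reference",
) -> "KdRatioResult":
    """KD/KD0 = slope_reference / slope_sample (crowded surfaces bind less,
    so a smaller sample slope means a ratio above 1)."""
    if not (reference_slope > 0):
        raise DomainError(f"reference slope must be positive, got {reference_slope}")
    if not (sample_slope > 0):
        raise DomainError(f"sample slope must be positive, got {sample_slope}")
    ratio = reference_slope / sample_slope
    rel = math.hypot(
        reference_se / reference_slope if reference_slope else 0.0,
        sample_se / sample_slope if sample_slope else 0.0,
    )
    energy = crowding_energy_from_kd_ratio(ratio, se_ratio=ratio * rel)
    return KdRatioResult(
        kd_ratio=ratio,
        se=ratio * rel,
        method="slope_ratio",
        reference_sample=reference_sample,
        delta_u_kBT=energy.delta_u_kBT,
        delta_u_se_kBT=energy.se_kBT,
    )


@dataclass(frozen=True)
class KdRatioResult:
    """A crowding-induced affinity shift with its uncertainty."""

    kd_ratio: float
    se: float
    method: str
    reference_sample: str
    delta_u_kBT: float
    delta_u_se_kBT: float

    @property
    def percent_increase(self) -> float:
        return 100.0 * (self.kd_ratio - 1.0)


@dataclass(frozen=True)
class LangmuirFit:
    """Nonlinear Langmuir fit θ̄ = Cmax·C/(C+KD) of one isotherm."""

    kd_nM: float
    kd_se_nM: float
    cmax: float
    cmax_se: float
    converged: bool
    ill_posed: bool
    message: str = ""


def fit_langmuir(isotherm: BindingIsotherm) -> LangmuirFit:
    """Full nonlinear least-squares Langmuir fit.

    Needs at least three concentrations; a KD landing outside the measured
    concentration range by more than 100× is flagged ill-posed rather than
    silently returned.
    """
    conc, theta = isotherm.conc_nM, isotherm.theta
    if len(conc) < 3:
        raise EstimationError(
            f"full Langmuir fit needs >= 3 concentrations, got {len(conc)}"
        )

    def model(c, cmax, kd):
        return cmax * c / (c + kd)

    p0 = (max(theta.max(), 1e-12) * 2.0, float(np.median(conc)))
    try:
        popt, pcov = optimize.curve_fit(
            model, conc, theta, p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10_000,
        )
        converged = True
        message = ""
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        return LangmuirFit(math.nan, math.nan, math.nan, math.nan,
                           converged=False, ill_posed=True, message=str(exc))
    cmax, kd = popt
    se = np.sqrt(np.diag(pcov))
    ill = not (conc.min() / 100.0 <= kd <= conc.max() * 100.0)
    if ill:
        message = (
            f"fitted KD={kd:.4g} nM lies outside the measured range "
            f"[{conc.min()}, {conc.max()}] nM by more than 100x"
        )
    return LangmuirFit(
        kd_nM=float(kd), kd_se_nM=float(se[1]), cmax=float(cmax), cmax_se=float(se[0]),
        converged=converged, ill_posed=ill, message=message,
    )


@dataclass
class PopulationCrowding:
    """Single-cell crowding distribution r_i = KD_i/KD_reference."""

    ratios: np.ndarray
    mean: float
    sd: float
    cv: float
    median: float
    q1: float
    q3: float
    n_cells: int
    n_excluded: int
    expression: Optional[np.ndarray] = None


def single_cell_crowding(
    events: pd.DataFrame,
    reference_events: pd.DataFrame,
    bulk_conc_nM: Optional[float] = None,
    reference_kd_nM: Optional[float] = None,
) -> PopulationCrowding:
    """Per-cell affinity ratios at one fixed, low bulk concentration.

    In the linear regime θ_i ≈ C/KD_i, so dividing the reference sample's
    mean normalized signal by each cell's normalized signal yields
    r_i ≈ KD_i/KD_ref.  Cells with zero normalized signal are excluded and
    counted.  If ``reference_kd_nM`` is given, the working concentration is
    checked against it (it should sit well below KD_ref).
    """
    for df, name in ((events, "events"), (reference_events, "reference_events")):
        if "norm_signal" not in df.columns:
            raise UsageError(f"{name}: run normalize_events first")
    concs = set(np.unique(events["bulk_conc_nM"])) | set(
        np.unique(reference_events["bulk_conc_nM"])
    )
    if bulk_conc_nM is None:
        if len(concs) != 1:
            raise UsageError(
                f"events span {len(concs)} bulk concentrations; pass bulk_conc_nM"
            )
        bulk_conc_nM = concs.pop()
    events = events[events["bulk_conc_nM"] == bulk_conc_nM]
    reference_events = reference_events[reference_events["bulk_conc_nM"] == bulk_conc_nM]
    if len(events) == 0 or len(reference_events) == 0:
        raise UsageError(f"no events at bulk concentration {bulk_conc_nM} nM")
    if reference_kd_nM is not None and bulk_conc_nM > 0.2 * reference_kd_nM:
        raise UsageError(
            f"bulk concentration {bulk_conc_nM} nM is not small against the "
            f"reference KD {reference_kd_nM} nM; single-cell ratios assume the "
            "linear regime (C < 0.2 KD)"
        )
    ref_mean = float(reference_events["norm_signal"].mean())
    signal = events["norm_signal"].to_numpy(float)
    positive = signal > 0
    ratios = ref_mean / signal[positive]
    if len(ratios) == 0:
        raise DataError("all cells have zero normalized signal")
    expr = events["expression"].to_numpy(float)[positive] if "expression" in events else None
    if expr is not None and not np.isfinite(expr).any():
        expr = None
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return PopulationCrowding(
        ratios=ratios,
        mean=mean,
        sd=sd,
        cv=sd / mean if mean else math.nan,
        median=float(np.median(ratios)),
        q1=float(np.quantile(ratios, 0.25)),
        q3=float(np.quantile(ratios, 0.75)),
        n_cells=int(len(ratios)),
        n_excluded=int((~positive).sum()),
        expression=expr,
    )


def bin_by_expression(
    population: PopulationCrowding,
    n_bins: int = 20,
    min_count: int = 10,
) -> pd.DataFrame:
    """Mean crowding ratio in log10-spaced expression bins.

    Returns a tidy frame with one row per bin; bins holding fewer than
    ``min_count`` cells are flagged ``excluded`` (listed, not dropped).
    """
    if population.expression is None:
        raise UsageError("population carries no expression channel")
    expr = population.expression
    ok = np.isfinite(expr) & (expr > 0)
    expr, ratios = expr[ok], population.ratios[ok]
    if len(expr) == 0:
        raise UsageError("no positive expression values to bin")
    edges = np.logspace(np.log10(expr.min()), np.log10(expr.max()), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12
    idx = np.clip(np.digitize(expr, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        vals = ratios[sel]
        rows.append(
            {
                "bin_center": math.sqrt(edges[b] * edges[b + 1]),
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_cells": n,
                "mean_ratio": float(vals.mean()) if n else math.nan,
                "se_ratio": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
                "excluded": n < min_count,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject, band


def significance_band(p: float) -> str:
    """Significance band: n.s., * (<0.05), ** (<0.01), *** (<0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare per-sample replicate means across conditions.

    ``groups`` maps condition name -> replicate-level values.  Every group
    needs at least two replicates.
    """
    if len(groups) < 2:
        raise UsageError(f"need >= 2 groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise UsageError(f"group {name!r} has a single replicate; need >= 2")
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    res = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    table["p-adj"] = res.pvalues
    table["band"] = [significance_band(pv) for pv in res.pvalues]
    return GroupComparison(anova_f=float(f_stat), anova_p=float(p), tukey=table)
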