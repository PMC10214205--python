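"""End-to-end study protocols.

Each function wires generators, simulator, and pipeline into one named
measurement: the simulated multidomain-brush affinity shift, slope-ratio
recovery of a known crowding factor from synthetic event tables, and
single-cell population recovery.  These are the package's headline
computations; the acceptance script and the test suite both run them.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from . import isotherm as iso
from . import synth
from .isotherm import KdRatioResult, PopulationCrowding
from .simulate import (
    SimulationConfig,
    chains_for_density,
    kd_ratio_from_profiles,
    sample_brush,
    widom_insertion_profile,
)
from .theory import CrowdingEnergy

__all__ = [
    "fib_brush_kd_ratio",
    "slope_ratio_recovery",
    "population_recovery",
]


def fib_brush_kd_ratio(
    beads_per_chain: int,
    seed: int,
    box_nm: float = 100.0,
    density_per_um2: float = 10_000.0,
    bead_nm: float = 4.0,
    probe_nm: float = 10.0,
    equil_tau: float = 10.0,
    n_frames: int = 100,
    spacing_tau: float = 0.2,
    n_insertions: int = 1_000_000,
) -> CrowdingEnergy:
    """Affinity shift of a hard probe at contact over a multidomain brush.

    Defaults reproduce the engineered-protein (Fibcon-like) surface: 4-nm
    domains grafted at 10,000 chains/µm² in a 100×100 nm periodic box
    (100 mobile-anchor chains), probed by a 10-nm sphere Widom-inserted at
    z = 5 nm over ≥100 decorrelated frames.
    """
    cfg = SimulationConfig(
        box_xy_nm=(box_nm, box_nm),
        n_chains=chains_for_density((box_nm, box_nm), density_per_um2),
        beads_per_chain=beads_per_chain,
        bead_diameter_nm=bead_nm,
        grafting_density_per_um2=density_per_um2,
        seed=seed,
    )
    frames = sample_brush(cfg, equil_time=equil_tau, n_frames=n_frames,
                          frame_interval=spacing_tau)
    z_b = probe_nm / 2.0
    crowded = widom_insertion_profile(
        frames, cfg.box_xy_nm, probe_nm, [z_b], n_insertions=n_insertions,
        seed=seed + 1, bead_diameter_nm=bead_nm,
    )
    bare = widom_insertion_profile(
        np.empty((1, 0, 3)), cfg.box_xy_nm, probe_nm, [z_b],
        n_insertions=1000, bead_diameter_nm=bead_nm,
    )
    return kd_ratio_from_profiles(crowded, bare)


def slope_ratio_recovery(
    kd0_nM: float,
    true_kd_ratio: float,
    concs_nM: Sequence[float],
    n_events_per_conc: int,
    seed: int,
    theta_cutoff: float = 0.2,
    n_bootstrap: int = 1000,
) -> KdRatioResult:
    """Generate a reference/crowded event-table pair and recover KD/KD0.

    Runs the full pipeline: per-event anchor normalization with gating,
    concentration grouping, weighted low-concentration slopes with bootstrap
    SEs, and the slope ratio.
    """
    events = synth.gen_isotherm_events(
        kd0_nM, true_kd_ratio, concs_nM, n_events_per_conc,
        synth.NoiseModel(seed=seed),
    )
    normed, _ = iso.normalize_events(events)
    ref = iso.build_isotherm(normed[normed["sample_id"] == "bare_bead"])
    crw = iso.build_isotherm(normed[normed["sample_id"] == "crowded"])
    s0, se0 = iso.low_conc_slope(ref, theta_cutoff, n_bootstrap, seed + 1)
    s1, se1 = iso.low_conc_slope(crw, theta_cutoff, n_bootstrap, seed + 2)
    return iso.kd_ratio_from_slopes(s0, s1, se0, se1, reference_sample="bare_bead")


def population_recovery(
    geometric_mean_ratio: float,
    cv: float,
    n_cells: int,
    seed: int,
    kd0_nM: float = 1.0,
    conc_over_kd0: float = 0.1,
) -> PopulationCrowding:
    """Generate a single-cell population and recover its crowding distribution.

    The population's per-cell KD/KD0 is lognormal with the given geometric
    mean and CV; measurement happens at a fixed bulk concentration of
    ``conc_over_kd0``·KD0 against a bare reference sample.
    """
    conc = conc_over_kd0 * kd0_nM
    events = synth.gen_population(
        geometric_mean_ratio, cv, n_cells, fixed_conc_nM=conc, kd0_nM=kd0_nM,
        noise=synth.NoiseModel(seed=seed),
    )
    normed, _ = iso.normalize_events(events)
    return iso.single_cell_crowding(
        normed[normed["sample_id"] == "cells"],
        normed[normed["sample_id"] == "bare_bead"],
        bulk_conc_nM=conc,
        reference_kd_nM=kd0_nM,
    )
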