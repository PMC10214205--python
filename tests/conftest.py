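"""Shared fixtures: equilibrated brush frames reused across test modules.

Simulations here run at desk scale (40-50 nm boxes, tens of chains, a few
hundred thousand steps); directional claims are tested against standard
errors measured from the same runs.
"""

from functools import lru_cache

import numpy as np
import pytest

from crowdsense.simulate import (
    SimulationConfig,
    YukawaConfig,
    build_system,
    sample_frames,
    step_dynamics,
)

BOX_NM = (50.0, 50.0)


@lru_cache(maxsize=None)
def brush_frames(
    beads_per_chain: int,
    n_chains: int,
    seed: int,
    debye_nm: float = 0.0,
    box_nm: float = 50.0,
    n_frames: int = 40,
    spacing_tau: float = 0.4,
    equil_tau: float = 8.0,
):
    """Equilibrate one brush and cache its frames for the whole session."""
    yuk = YukawaConfig(amplitude_kBT=2.0, debye_length_nm=debye_nm) if debye_nm else None
    cfg = SimulationConfig(
        box_xy_nm=(box_nm, box_nm),
        n_chains=n_chains,
        beads_per_chain=beads_per_chain,
        bead_diameter_nm=4.0,
        seed=seed,
        yukawa=yuk,
    )
    state = build_system(cfg)
    step_dynamics(state, int(equil_tau / cfg.timestep))
    frames = sample_frames(state, n_frames, int(spacing_tau / cfg.timestep))
    frames.setflags(write=False)
    return frames


@pytest.fixture(scope="session")
def dense_frames_by_length():
    """N = 1, 3, 5 bead chains at ~10,000 chains/µm² (25 chains, 50×50 nm)."""
    return {n: brush_frames(n, 25, seed=100 + n) for n in (1, 3, 5)}


@pytest.fixture(scope="session")
def n3_frames_by_density():
    """3-bead chains at 2,000 / 6,000 / 10,000 chains/µm²."""
    return {
        2000: brush_frames(3, 5, seed=201),
        6000: brush_frames(3, 15, seed=202),
        10000: brush_frames(3, 25, seed=203),
    }


@pytest.fixture(scope="session")
def charged_frames_by_debye():
    """5-bead chains at ~15,000/µm² (24 chains, 40×40 nm): uncharged and
    Yukawa-charged with 1 and 2 nm Debye lengths."""
    kw = dict(box_nm=40.0, n_frames=30, spacing_tau=0.5, equil_tau=8.0)
    return {
        0.0: brush_frames(5, 24, seed=301, debye_nm=0.0, **kw),
        1.0: brush_frames(5, 24, seed=302, debye_nm=1.0, **kw),
        2.0: brush_frames(5, 24, seed=303, debye_nm=2.0, **kw),
    }


@pytest.fixture(scope="session")
def bare_frames():
    """A bare wall: one frame with zero beads."""
    return np.empty((1, 0, 3))
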