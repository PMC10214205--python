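"""System construction, integration, and frame sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import NumericalError
from .config import SimulationConfig
from .kernels import step_block

__all__ = ["SimulationState", "build_system", "step_dynamics", "sample_frames", "sample_brush"]

#: FENE+WCA equilibrium bond length in σ units (Kremer–Grest, k=30, R0=1.5).
BOND_EQ = 0.97


@dataclass
class SimulationState:
    """Mutable state of one simulation.

    ``positions`` are reduced coordinates (σ units), chains stored
    consecutively with the anchor as bead 0 of each chain.  ``block`` counts
    integration calls; together with the config seed it determines the RNG
    stream of the next call, so trajectories are bit-reproducible.
    """

    config: SimulationConfig
    positions: np.ndarray
    step: int = 0
    block: int = 0

    @property
    def positions_nm(self) -> np.ndarray:
        return self.positions * self.config.sigma_nm

    def bond_lengths(self) -> np.ndarray:
        npc = self.config.beads_per_chain
        if npc < 2 or self.config.n_chains == 0:
            return np.empty(0)
        pos = self.positions.reshape(self.config.n_chains, npc, 3)
        d = pos[:, 1:, :] - pos[:, :-1, :]
        bx, by = (np.asarray(self.config.box_xy_nm) / self.config.sigma_nm)
        d[..., 0] -= bx * np.rint(d[..., 0] / bx)
        d[..., 1] -= by * np.rint(d[..., 1] / by)
        return np.sqrt((d**2).sum(axis=-1)).ravel()


def build_system(config: SimulationConfig) -> SimulationState:
    """Place anchors uniformly at random and stand chains up as jittered rods.

    Deterministic for a fixed config seed.  Raises ``ConfigurationError`` when
    a requested grafting density disagrees with box area × chain count by
    more than one chain.
    """
    config.check_density()
    sigma = config.sigma_nm
    bx, by = config.box_xy_nm[0] / sigma, config.box_xy_nm[1] / sigma
    rng = np.random.default_rng(config.seed)
    n = config.n_beads
    pos = np.empty((n, 3))
    npc = config.beads_per_chain
    anchors = np.empty((config.n_chains, 2))
    # rejection-sample anchor sites so no two chains start overlapped; fall
    # back to the farthest candidate seen when the surface is nearly jammed
    min_sep2 = 0.9**2
    for c in range(config.n_chains):
        best, best_d2 = None, -1.0
        for _attempt in range(200):
            cand = np.array([rng.uniform(0.0, bx), rng.uniform(0.0, by)])
            if c == 0:
                best = cand
                break
            d = anchors[:c] - cand
            d[:, 0] -= bx * np.rint(d[:, 0] / bx)
            d[:, 1] -= by * np.rint(d[:, 1] / by)
            d2 = float((d**2).sum(axis=1).min())
            if d2 > best_d2:
                best, best_d2 = cand, d2
            if d2 >= min_sep2:
                break
        anchors[c] = best
    for c in range(config.n_chains):
        ax, ay = anchors[c]
        for k in range(npc):
            i = c * npc + k
            jx, jy = (rng.normal(0.0, 0.01), rng.normal(0.0, 0.01)) if k else (0.0, 0.0)
            pos[i, 0] = (ax + jx) % bx
            pos[i, 1] = (ay + jy) % by
            pos[i, 2] = 0.5 + BOND_EQ * k
    return SimulationState(config=config, positions=pos)


def _block_seed(config_seed: int, block: int) -> int:
    return int(np.random.SeedSequence([config_seed & 0x7FFFFFFF, block]).generate_state(1)[0]
               & 0x7FFFFFFF)


def step_dynamics(state: SimulationState, n_steps: int) -> SimulationState:
    """Advance the overdamped Langevin dynamics by ``n_steps`` (in place)."""
    if n_steps <= 0:
        return state
    cfg = state.config
    if cfg.n_beads == 0:
        state.step += n_steps
        state.block += 1
        return state
    sigma = cfg.sigma_nm
    yuk_a, yuk_kappa, yuk_cut2 = cfg.yukawa_reduced()
    slab = (cfg.slab_height_nm / sigma) if cfg.slab_height_nm else 0.0
    status, at_step, chain = step_block(
        state.positions,
        cfg.beads_per_chain,
        cfg.box_xy_nm[0] / sigma,
        cfg.box_xy_nm[1] / sigma,
        cfg.fene_k,
        cfg.fene_r0**2,
        cfg.wca_epsilon_kBT,
        cfg.bending_stiffness_kBT,
        yuk_a,
        yuk_kappa,
        yuk_cut2,
        cfg.timestep,
        cfg.friction,
        1.0,
        n_steps,
        _block_seed(cfg.seed, state.block),
        cfg.tethered,
        cfg.anchor_mobile,
        cfg.wall,
        cfg.ideal,
        slab,
    )
    if status == 1:
        raise NumericalError(
            f"FENE bond on chain {chain} reached maximum extension at step "
            f"{state.step + at_step}; reduce the timestep"
        )
    state.step += n_steps
    state.block += 1
    return state


def sample_frames(state: SimulationState, n_frames: int, steps_between: int) -> np.ndarray:
    """Advance the dynamics, harvesting ``n_frames`` snapshots in nm.

    Returns an array of shape (n_frames, n_beads, 3).
    """
    frames = np.empty((n_frames, state.config.n_beads, 3))
    for f in range(n_frames):
        step_dynamics(state, steps_between)
        frames[f] = state.positions_nm
    return frames


def sample_brush(
    config: SimulationConfig,
    equil_time: float = 10.0,
    n_frames: int = 100,
    frame_interval: float = 0.2,
) -> np.ndarray:
    """Equilibrate a brush and return decorrelated frames (nm).

    Times are in reduced diffusion times τ = σ²γ/kBT; with the default
    Δt = 10⁻⁴ τ, ``equil_time=10`` is 10⁵ steps — ample for the short grafted
    chains modelled here (contour ≤ ~6 σ).
    """
    state = build_system(config)
    step_dynamics(state, int(round(equil_time / config.timestep)))
    return sample_frames(state, n_frames, int(round(frame_interval / config.timestep)))
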