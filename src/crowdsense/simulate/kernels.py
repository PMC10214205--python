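"""Numba kernels: the Brownian-dynamics inner loop and Widom insertion.

All kernels work in reduced units (σ = 1, kBT = 1) except the Widom kernels,
which are unit-agnostic as long as positions, box, and contact distances are
consistent.  Kernels seed numba's RNG explicitly on entry, so a fixed seed
gives bit-identical output regardless of call order elsewhere in the process.
"""

import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared cutoff (2^{1/6} σ)²


@njit(cache=True, fastmath=True)
def step_block(pos, npc, box_x, box_y, fene_k, fene_r0_sq, wca_eps, kbend,
               yuk_a, yuk_kappa, yuk_cut2, dt, gamma, kT, n_steps, seed,
               tethered, anchor_mobile, wall_on, ideal, slab_h):
    """Integrate ``n_steps`` of overdamped Langevin dynamics in place.

    Chains are stored consecutively; bead ``c*npc`` is chain c's anchor.
    Returns (status, step, chain): status 0 on success, 1 when a FENE bond
    reached its maximum extension (integration failure).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nch = n // npc
    forces = np.zeros((n, 3))
    mob = dt / gamma
    noise_amp = np.sqrt(2.0 * kT * dt / gamma)
    wall_sig2 = 0.25
    wall_cut = 0.5 * 2.0 ** (1.0 / 6.0)
    inv_bx = 1.0 / box_x
    inv_by = 1.0 / box_y
    pair_cut2 = WCA_CUT2 if yuk_cut2 < WCA_CUT2 else yuk_cut2

    for step in range(n_steps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0

        if not ideal:
            # nonbonded: WCA (+ optional Yukawa) over all pairs
            for i in range(n - 1):
                xi = pos[i, 0]
                yi = pos[i, 1]
                zi = pos[i, 2]
                for j in range(i + 1, n):
                    dz = zi - pos[j, 2]
                    if dz * dz >= pair_cut2:
                        continue
                    dx = xi - pos[j, 0]
                    dy = yi - pos[j, 1]
                    dx -= box_x * np.rint(dx * inv_bx)
                    dy -= box_y * np.rint(dy * inv_by)
                    r2 = dx * dx + dy * dy + dz * dz
                    fmag = 0.0
                    if r2 < WCA_CUT2:
                        inv2 = 1.0 / r2
                        inv6 = inv2 * inv2 * inv2
                        fmag += wca_eps * (48.0 * inv6 * inv6 - 24.0 * inv6) * inv2
                    if yuk_a != 0.0 and r2 < yuk_cut2:
                        r = np.sqrt(r2)
                        u = yuk_a / r * np.exp(-yuk_kappa * (r - 1.0))
                        fmag += u * (1.0 / r + yuk_kappa) / r
                    if fmag != 0.0:
                        forces[i, 0] += fmag * dx
                        forces[i, 1] += fmag * dy
                        forces[i, 2] += fmag * dz
                        forces[j, 0] -= fmag * dx
                        forces[j, 1] -= fmag * dy
                        forces[j, 2] -= fmag * dz

            # FENE bonds along each chain
            for c in range(nch):
                base = c * npc
                for k in range(npc - 1):
                    i = base + k
                    j = i + 1
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    dx -= box_x * np.rint(dx / box_x)
                    dy -= box_y * np.rint(dy / box_y)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= fene_r0_sq:
                        return 1, step, c
                    fmag = -fene_k / (1.0 - r2 / fene_r0_sq)
                    forces[i, 0] += fmag * dx
                    forces[i, 1] += fmag * dy
                    forces[i, 2] += fmag * dz
                    forces[j, 0] -= fmag * dx
                    forces[j, 1] -= fmag * dy
                    forces[j, 2] -= fmag * dz

                # cosine bending U = k_b (1 - cos φ) between successive bonds
                if kbend > 0.0:
                    for k in range(npc - 2):
                        a = base + k
                        b = a + 1
                        cc = b + 1
                        r1x = pos[b, 0] - pos[a, 0]
                        r1y = pos[b, 1] - pos[a, 1]
                        r1z = pos[b, 2] - pos[a, 2]
                        r1x -= box_x * np.rint(r1x / box_x)
                        r1y -= box_y * np.rint(r1y / box_y)
                        r2x = pos[cc, 0] - pos[b, 0]
                        r2y = pos[cc, 1] - pos[b, 1]
                        r2z = pos[cc, 2] - pos[b, 2]
                        r2x -= box_x * np.rint(r2x / box_x)
                        r2y -= box_y * np.rint(r2y / box_y)
                        n1sq = r1x * r1x + r1y * r1y + r1z * r1z
                        n2sq = r2x * r2x + r2y * r2y + r2z * r2z
                        inv12 = 1.0 / np.sqrt(n1sq * n2sq)
                        dot = r1x * r2x + r1y * r2y + r1z * r2z
                        cphi = dot * inv12
                        # d cosφ / d r1 and / d r2
                        g1x = r2x * inv12 - cphi * r1x / n1sq
                        g1y = r2y * inv12 - cphi * r1y / n1sq
                        g1z = r2z * inv12 - cphi * r1z / n1sq
                        g2x = r1x * inv12 - cphi * r2x / n2sq
                        g2y = r1y * inv12 - cphi * r2y / n2sq
                        g2z = r1z * inv12 - cphi * r2z / n2sq
                        forces[a, 0] -= kbend * g1x
                        forces[a, 1] -= kbend * g1y
                        forces[a, 2] -= kbend * g1z
                        forces[cc, 0] += kbend * g2x
                        forces[cc, 1] += kbend * g2y
                        forces[cc, 2] += kbend * g2z
                        forces[b, 0] += kbend * (g1x - g2x)
                        forces[b, 1] += kbend * (g1y - g2y)
                        forces[b, 2] += kbend * (g1z - g2z)

        if wall_on:
            # WCA-form wall in z on every bead (σ_wall = σ/2)
            for i in range(n):
                z = pos[i, 2]
                if 0.0 < z < wall_cut:
                    s2 = wall_sig2 / (z * z)
                    s6 = s2 * s2 * s2
                    forces[i, 2] += 24.0 * (2.0 * s6 * s6 - s6) / z

        for i in range(n):
            if tethered and i % npc == 0:
                if anchor_mobile:
                    pos[i, 0] += forces[i, 0] * mob + noise_amp * np.random.standard_normal()
                    pos[i, 1] += forces[i, 1] * mob + noise_amp * np.random.standard_normal()
            else:
                pos[i, 0] += forces[i, 0] * mob + noise_amp * np.random.standard_normal()
                pos[i, 1] += forces[i, 1] * mob + noise_amp * np.random.standard_normal()
                pos[i, 2] += forces[i, 2] * mob + noise_amp * np.random.standard_normal()
                if slab_h > 0.0:
                    if pos[i, 2] > slab_h:
                        pos[i, 2] = 2.0 * slab_h - pos[i, 2]
                    if pos[i, 2] < 0.0:
                        pos[i, 2] = -pos[i, 2]
            pos[i, 0] -= box_x * np.floor(pos[i, 0] / box_x)
            pos[i, 1] -= box_y * np.floor(pos[i, 1] / box_y)

    return 0, n_steps, -1


@njit(cache=True)
def widom_hard_count(frames, box_x, box_y, z_probe, contact2, n_per_frame, seed):
    """Count non-overlapping hard-sphere insertions at height ``z_probe``.

    ``frames`` has shape (n_frames, n_beads, 3); xy insertion points are
    uniform over the periodic box.  Returns (accepted, attempted).
    """
    np.random.seed(seed)
    nf = frames.shape[0]
    nb = frames.shape[1]
    ok = 0
    total = 0
    for fi in range(nf):
        for _t in range(n_per_frame):
            x = np.random.random() * box_x
            y = np.random.random() * box_y
            hit = False
            for b in range(nb):
                dx = frames[fi, b, 0] - x
                dy = frames[fi, b, 1] - y
                dz = frames[fi, b, 2] - z_probe
                dx -= box_x * np.rint(dx / box_x)
                dy -= box_y * np.rint(dy / box_y)
                if dx * dx + dy * dy + dz * dz < contact2:
                    hit = True
                    break
            if not hit:
                ok += 1
            total += 1
    return ok, total


@njit(cache=True)
def widom_soft_weights(frames, box_x, box_y, z_probe, sigma_mix, eps, n_per_frame, seed):
    """Boltzmann insertion weights exp(−βΔE) for a WCA (soft) probe.

    Returns (sum of weights, sum of squared weights, attempts) for the mean
    and its standard error.
    """
    np.random.seed(seed)
    nf = frames.shape[0]
    nb = frames.shape[1]
    cut2 = WCA_CUT2 * sigma_mix * sigma_mix
    s2ref = sigma_mix * sigma_mix
    wsum = 0.0
    w2sum = 0.0
    total = 0
    for fi in range(nf):
        for _t in range(n_per_frame):
            x = np.random.random() * box_x
            y = np.random.random() * box_y
            e = 0.0
            for b in range(nb):
                dx = frames[fi, b, 0] - x
                dy = frames[fi, b, 1] - y
                dz = frames[fi, b, 2] - z_probe
                dx -= box_x * np.rint(dx / box_x)
                dy -= box_y * np.rint(dy / box_y)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cut2:
                    s6 = (s2ref / r2) ** 3
                    e += 4.0 * eps * (s6 * s6 - s6) + eps
                    if e > 50.0:
                        break
            w = np.exp(-e) if e < 50.0 else 0.0
            wsum += w
            w2sum += w * w
            total += 1
    return wsum, w2sum, total
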