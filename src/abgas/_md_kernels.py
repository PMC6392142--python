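"""BAOAB Langevin integrator for the coarse-grained vacuum collapse model."""

import numpy as np
from numba import njit


@njit(cache=True)
def _forces(
    x,
    f,
    bond_i,
    bond_j,
    bond_r0,
    bond_k,
    en_i,
    en_j,
    en_r0,
    en_k,
    excl,
    lj_eps,
    lj_sigma,
    lj_cutoff,
    q_idx,
    q_val,
    kcoul,
    fcap,
):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    # harmonic chain bonds
    for b in range(bond_i.size):
        i, j = bond_i[b], bond_j[b]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        if r > 1e-10:
            fm = -2.0 * bond_k * (r - bond_r0[b]) / r
            f[i, 0] += fm * dx0
            f[i, 1] += fm * dx1
            f[i, 2] += fm * dx2
            f[j, 0] -= fm * dx0
            f[j, 1] -= fm * dx1
            f[j, 2] -= fm * dx2
    # elastic network inside rigid bodies
    for b in range(en_i.size):
        i, j = en_i[b], en_j[b]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        if r > 1e-10:
            fm = -2.0 * en_k * (r - en_r0[b]) / r
            f[i, 0] += fm * dx0
            f[i, 1] += fm * dx1
            f[i, 2] += fm * dx2
            f[j, 0] -= fm * dx0
            f[j, 1] -= fm * dx1
            f[j, 2] -= fm * dx2
    # soft 6-3 cohesion between all non-excluded pairs (well depth lj_eps at
    # r = lj_sigma), short range capped
    cutoff2 = lj_cutoff * lj_cutoff
    s3 = lj_sigma * lj_sigma * lj_sigma
    for i in range(n):
        xi0 = x[i, 0]
        xi1 = x[i, 1]
        xi2 = x[i, 2]
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx0 = xi0 - x[j, 0]
            dx1 = xi1 - x[j, 1]
            dx2 = xi2 - x[j, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 > cutoff2 or r2 < 1e-12:
                continue
            sr3 = s3 / (r2 * np.sqrt(r2))
            fm = 6.0 * lj_eps * (sr3 * sr3 - sr3) / r2
            cap = fcap / np.sqrt(r2)
            if fm > cap:
                fm = cap
            f[i, 0] += fm * dx0
            f[i, 1] += fm * dx1
            f[i, 2] += fm * dx2
            f[j, 0] -= fm * dx0
            f[j, 1] -= fm * dx1
            f[j, 2] -= fm * dx2
    # Coulomb repulsion between charged sites (vacuum, no cutoff)
    for a in range(q_idx.size):
        for b in range(a + 1, q_idx.size):
            i, j = q_idx[a], q_idx[b]
            dx0 = x[i, 0] - x[j, 0]
            dx1 = x[i, 1] - x[j, 1]
            dx2 = x[i, 2] - x[j, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 < 1.0:
                r2 = 1.0
            fm = kcoul * q_val[a] * q_val[b] / (r2 * np.sqrt(r2))
            f[i, 0] += fm * dx0
            f[i, 1] += fm * dx1
            f[i, 2] += fm * dx2
            f[j, 0] -= fm * dx0
            f[j, 1] -= fm * dx1
            f[j, 2] -= fm * dx2


@njit(cache=True)
def run_langevin(
    x0,
    masses,
    bond_i,
    bond_j,
    bond_r0,
    bond_k,
    en_i,
    en_j,
    en_r0,
    en_k,
    excl,
    lj_eps,
    lj_sigma,
    lj_cutoff,
    q_idx,
    q_val,
    kcoul,
    kT,
    gamma,
    dt,
    n_steps,
    report_stride,
    seed,
    fcap,
):
    """BAOAB Langevin splitting; returns strided frames incl. the initial one.

    Returns (frames, status): status is -1 on success, else the step index at
    which a non-finite coordinate appeared.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = np.empty((n, 3))
    for i in range(n):
        s = np.sqrt(kT / masses[i])
        for d in range(3):
            v[i, d] = s * np.random.standard_normal()
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    n_frames = n_steps // report_stride + 1
    frames = np.empty((n_frames, n, 3))
    frames[0] = x
    f = np.empty((n, 3))
    _forces(
        x, f, bond_i, bond_j, bond_r0, bond_k, en_i, en_j, en_r0, en_k, excl,
        lj_eps, lj_sigma, lj_cutoff, q_idx, q_val, kcoul, fcap,
    )
    frame = 1
    half_dt = 0.5 * dt
    for step in range(1, n_steps + 1):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            s = np.sqrt(kT * inv_m)
            for d in range(3):
                vv = v[i, d] + half_dt * f[i, d] * inv_m
                x[i, d] += half_dt * vv
                vv = c1 * vv + c2 * s * np.random.standard_normal()
                x[i, d] += half_dt * vv
                v[i, d] = vv
        _forces(
            x, f, bond_i, bond_j, bond_r0, bond_k, en_i, en_j, en_r0, en_k, excl,
            lj_eps, lj_sigma, lj_cutoff, q_idx, q_val, kcoul, fcap,
        )
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += half_dt * f[i, d] * inv_m
        if step % report_stride == 0:
            if not np.all(np.isfinite(x)):
                return frames[:frame], step
            frames[frame] = x
            frame += 1
    return frames[:frame], -1
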