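"""Numba-compiled Euler-Maruyama inner loops for the 1D Langevin simulator.

The matched-harmonic potential enters analytically; MetaD/OPES bias forces
are looked up from a uniform CV grid (linear interpolation of the bias, so
the force is piecewise constant within a grid cell).  Bias values logged in
the trajectory's trace are evaluated exactly (hill sums / grid bias at the
walker position) so they can be cross-checked against the Python bias
engines.  Each walker seeds its own RNG stream, making ensembles
reproducible and order-independent.
"""

import numpy as np
from numba import njit

ERR_NONE = 0
ERR_NONFINITE = 1


@njit(cache=True)
def _force_potential(x, x0, x1, xb, kappa):
    if x < xb:
        return -kappa * (x - x0)
    return kappa * (x - x1)


@njit(cache=True)
def walk_unbiased(seed, x_init, dt, d_coef, kbt, x0, x1, xb, kappa,
                  absorb, max_steps, record_stride):
    """One unbiased walker; optionally records positions every ``record_stride``
    steps.  Returns (time, transitioned, traj[:k], err, err_step)."""
    np.random.seed(seed)
    mob = d_coef / kbt * dt
    sq = np.sqrt(2.0 * d_coef * dt)
    nrec = max_steps // record_stride + 2 if record_stride > 0 else 1
    traj = np.empty(nrec)
    k = 0
    x = x_init
    if record_stride > 0:
        traj[0] = x
        k = 1
    for step in range(1, max_steps + 1):
        x = x + mob * _force_potential(x, x0, x1, xb, kappa) \
            + sq * np.random.standard_normal()
        if not np.isfinite(x):
            return step * dt, False, traj[:k], ERR_NONFINITE, step
        if record_stride > 0 and step % record_stride == 0:
            traj[k] = x
            k += 1
        if x >= absorb:
            return step * dt, True, traj[:k], ERR_NONE, step
    return max_steps * dt, False, traj[:k], ERR_NONE, max_steps


@njit(cache=True)
def _hills_value(x, centers, heights, nh, sigma):
    v = 0.0
    inv2s2 = 0.5 / (sigma * sigma)
    for j in range(nh):
        d = x - centers[j]
        v += heights[j] * np.exp(-d * d * inv2s2)
    return v


@njit(cache=True)
def walk_metad(seed, x_init, dt, d_coef, kbt, x0, x1, xb, kappa,
               absorb, max_steps, pace, h0, sigma, inv_kbdt,
               log_stride, gx0, gdx, ngrid):
    """One WT-MetaD walker.  ``inv_kbdt`` = 1/(kB*DeltaT); 0 means untempered.

    Hills are deposited at the walker position every ``pace`` steps with
    height h0*exp(-V/(kB DeltaT)) where V is the exact current hill sum at
    that position.  Forces use a gridded copy of the bias; the experienced
    bias V(x(t), t) is logged as an exact hill sum every ``log_stride``
    steps, at each deposition (including the fresh hill) and at termination.
    Returns (time, transitioned, hill_t, hill_c, hill_h,
    trace_t, trace_x, trace_v, err, step).
    """
    np.random.seed(seed)
    mob_dt = d_coef / kbt * dt
    sq = np.sqrt(2.0 * d_coef * dt)
    grid = np.zeros(ngrid)
    max_hills = max_steps // pace + 1
    hill_t = np.empty(max_hills)
    hill_c = np.empty(max_hills)
    hill_h = np.empty(max_hills)
    max_log = max_steps // log_stride + max_hills + 3
    tr_t = np.empty(max_log)
    tr_x = np.empty(max_log)
    tr_v = np.empty(max_log)
    nh = 0
    tr_t[0] = 0.0
    tr_x[0] = x_init
    tr_v[0] = 0.0
    nt = 1
    x = x_init
    win = 6.0 * sigma
    inv2s2 = 0.5 / (sigma * sigma)
    for step in range(1, max_steps + 1):
        f = _force_potential(x, x0, x1, xb, kappa)
        i = int((x - gx0) / gdx)
        if i < 0:
            i = 0
        elif i > ngrid - 2:
            i = ngrid - 2
        f += -(grid[i + 1] - grid[i]) / gdx
        x = x + mob_dt * f + sq * np.random.standard_normal()
        if not np.isfinite(x):
            return (step * dt, False, hill_t[:nh], hill_c[:nh], hill_h[:nh],
                    tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONFINITE, step)
        if x >= absorb:
            t_end = step * dt
            tr_t[nt] = t_end
            tr_x[nt] = x
            tr_v[nt] = _hills_value(x, hill_c, hill_h, nh, sigma)
            nt += 1
            return (t_end, True, hill_t[:nh], hill_c[:nh], hill_h[:nh],
                    tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONE, step)
        logged = False
        if step % pace == 0:
            t = step * dt
            v_here = _hills_value(x, hill_c, hill_h, nh, sigma)
            heff = h0 * np.exp(-v_here * inv_kbdt)
            hill_t[nh] = t
            hill_c[nh] = x
            hill_h[nh] = heff
            nh += 1
            jlo = int((x - win - gx0) / gdx)
            jhi = int((x + win - gx0) / gdx) + 1
            if jlo < 0:
                jlo = 0
            if jhi > ngrid:
                jhi = ngrid
            for j in range(jlo, jhi):
                d = gx0 + j * gdx - x
                grid[j] += heff * np.exp(-d * d * inv2s2)
            tr_t[nt] = t
            tr_x[nt] = x
            tr_v[nt] = v_here + heff
            nt += 1
            logged = True
        if step % log_stride == 0 and not logged:
            tr_t[nt] = step * dt
            tr_x[nt] = x
            tr_v[nt] = _hills_value(x, hill_c, hill_h, nh, sigma)
            nt += 1
    t_end = max_steps * dt
    if tr_t[nt - 1] < t_end:
        tr_t[nt] = t_end
        tr_x[nt] = x
        tr_v[nt] = _hills_value(x, hill_c, hill_h, nh, sigma)
        nt += 1
    return (t_end, False, hill_t[:nh], hill_c[:nh], hill_h[:nh],
            tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONE, max_steps)


@njit(cache=True)
def _opes_refresh(grid_v, kde, ngrid, cfac, eps):
    pmax = 0.0
    for j in range(ngrid):
        if kde[j] > pmax:
            pmax = kde[j]
    if pmax <= 0.0:
        for j in range(ngrid):
            grid_v[j] = 0.0
        return
    for j in range(ngrid):
        p = kde[j] / pmax
        grid_v[j] = cfac * np.log((p * (1.0 - eps) + eps) / eps)


@njit(cache=True)
def walk_opes(seed, x_init, dt, d_coef, kbt, x0, x1, xb, kappa,
              absorb, max_steps, pace, ksigma, cfac, eps,
              has_excl, excl_lo, excl_hi, log_stride, gx0, gdx, ngrid):
    """One OPES-flooding walker.

    Every ``pace`` steps a Gaussian kernel at the walker position joins the
    on-the-fly KDE (skipped inside the exclusion region) and the bias grid is
    refreshed as V = cfac*log((phat*(1-eps)+eps)/eps) with phat the KDE
    normalized by its maximum; cfac = (1-1/lambda)*kBT.  The bias is 0 where
    the KDE vanishes and exactly DeltaE at the KDE maximum, so its range
    never exceeds DeltaE.  The experienced bias is logged every
    ``log_stride`` steps, at each update and at termination.  Returns
    (time, transitioned, kern_t, kern_c, trace_t, trace_x, trace_v, err, step).
    """
    np.random.seed(seed)
    mob_dt = d_coef / kbt * dt
    sq = np.sqrt(2.0 * d_coef * dt)
    kde = np.zeros(ngrid)
    grid_v = np.zeros(ngrid)
    max_k = max_steps // pace + 1
    kern_t = np.empty(max_k)
    kern_c = np.empty(max_k)
    max_log = max_steps // log_stride + max_k + 3
    tr_t = np.empty(max_log)
    tr_x = np.empty(max_log)
    tr_v = np.empty(max_log)
    nk = 0
    tr_t[0] = 0.0
    tr_x[0] = x_init
    tr_v[0] = 0.0
    nt = 1
    x = x_init
    win = 6.0 * ksigma
    inv2s2 = 0.5 / (ksigma * ksigma)
    for step in range(1, max_steps + 1):
        f = _force_potential(x, x0, x1, xb, kappa)
        i = int((x - gx0) / gdx)
        if i < 0:
            i = 0
        elif i > ngrid - 2:
            i = ngrid - 2
        f += -(grid_v[i + 1] - grid_v[i]) / gdx
        x = x + mob_dt * f + sq * np.random.standard_normal()
        if not np.isfinite(x):
            return (step * dt, False, kern_t[:nk], kern_c[:nk],
                    tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONFINITE, step)
        if x >= absorb:
            t_end = step * dt
            i = min(max(int((x - gx0) / gdx), 0), ngrid - 2)
            frac = (x - gx0) / gdx - i
            tr_t[nt] = t_end
            tr_x[nt] = x
            tr_v[nt] = grid_v[i] + frac * (grid_v[i + 1] - grid_v[i])
            nt += 1
            return (t_end, True, kern_t[:nk], kern_c[:nk],
                    tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONE, step)
        logged = False
        if step % pace == 0:
            t = step * dt
            excluded = has_excl and (excl_lo <= x <= excl_hi)
            if not excluded:
                jlo = int((x - win - gx0) / gdx)
                jhi = int((x + win - gx0) / gdx) + 1
                if jlo < 0:
                    jlo = 0
                if jhi > ngrid:
                    jhi = ngrid
                for j in range(jlo, jhi):
                    d = gx0 + j * gdx - x
                    kde[j] += np.exp(-d * d * inv2s2)
                kern_t[nk] = t
                kern_c[nk] = x
                nk += 1
                _opes_refresh(grid_v, kde, ngrid, cfac, eps)
            i = min(max(int((x - gx0) / gdx), 0), ngrid - 2)
            frac = (x - gx0) / gdx - i
            tr_t[nt] = t
            tr_x[nt] = x
            tr_v[nt] = grid_v[i] + frac * (grid_v[i + 1] - grid_v[i])
            nt += 1
            logged = True
        if step % log_stride == 0 and not logged:
            i = min(max(int((x - gx0) / gdx), 0), ngrid - 2)
            frac = (x - gx0) / gdx - i
            tr_t[nt] = step * dt
            tr_x[nt] = x
            tr_v[nt] = grid_v[i] + frac * (grid_v[i + 1] - grid_v[i])
            nt += 1
    t_end = max_steps * dt
    if tr_t[nt - 1] < t_end:
        i = min(max(int((x - gx0) / gdx), 0), ngrid - 2)
        frac = (x - gx0) / gdx - i
        tr_t[nt] = t_end
        tr_x[nt] = x
        tr_v[nt] = grid_v[i] + frac * (grid_v[i + 1] - grid_v[i])
        nt += 1
    return (t_end, False, kern_t[:nk], kern_c[:nk],
            tr_t[:nt], tr_x[:nt], tr_v[:nt], ERR_NONE, max_steps)
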