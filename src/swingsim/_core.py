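"""Numba-compiled numerical kernels.

Everything here is private plumbing: the public modules (`dynamics`,
`assistance`, `protocol`) wrap these kernels with validated, documented
interfaces.  All kernels are deterministic — randomness (motor noise, target
jitter) is drawn outside and passed in as arrays.

State vector layout used throughout: ``s = [y, z, y_dot, z_dot, theta,
theta_dot]`` (pivot position/velocity in m and m/s, pendulum angle in rad,
positive counter-clockwise from straight down).

Assist application point encoding: 0 = none, 1 = end-effector, 2 = ball.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# coupled pivot + pendulum accelerations
# ---------------------------------------------------------------------------


@njit(cache=True)
def accels(y, z, yd, zd, th, thd, f_py, f_pz, f_ball,
           m, l, g, c, m_ee, b_ee, clamped):
    """Accelerations of the coupled pivot/pendulum system.

    ``f_py``/``f_pz`` are external forces on the pivot (hand + any assist
    applied at the end-effector); ``f_ball`` is a horizontal force applied
    directly at the ball.  Returns ``(ydd, zdd, thdd, f_rod)`` where
    ``f_rod`` is the scalar rod force (tension positive) felt at the pivot
    along the pivot->ball direction ``(sin th, -cos th)``.

    The rod force couples pivot and swing dynamics, so with a free pivot the
    two pivot accelerations come from a 2x2 linear solve (the classic
    cart-pendulum inertia coupling).
    """
    s = np.sin(th)
    ct = np.cos(th)

    if m <= 0.0:
        # pendulum removed: pivot is a plain forced damped mass
        ydd = (f_py - b_ee * yd) / m_ee
        zdd = (f_pz - b_ee * zd) / m_ee
        if clamped:
            ydd = 0.0
            zdd = 0.0
        return ydd, zdd, 0.0, 0.0

    if clamped:
        ydd = 0.0
        zdd = 0.0
    else:
        # centripetal + gravity part of the rod tension (z̈/ÿ folded in below)
        base = m * (g * ct + l * thd * thd)
        a11 = m_ee + m * s * s
        a12 = -m * s * ct
        a22 = m_ee + m * ct * ct
        r1 = f_py - b_ee * yd + s * base + f_ball * s * s
        r2 = f_pz - b_ee * zd - ct * base - f_ball * s * ct
        det = a11 * a22 - a12 * a12
        ydd = (a22 * r1 - a12 * r2) / det
        zdd = (a11 * r2 - a12 * r1) / det

    f_rod = m * ((zdd + g) * ct - ydd * s + thd * thd * l) + f_ball * s
    thdd = (-((zdd + g) * s + ydd * ct) / l
            - c / (m * l * l) * thd
            + f_ball * ct / (m * l))
    return ydd, zdd, thdd, f_rod


@njit(cache=True)
def rk4_step(s, f_py, f_pz, f_ball, dt, m, l, g, c, m_ee, b_ee, clamped):
    """One fixed-step RK4 update of the 6-state system; forces held constant."""
    out = np.empty(6)

    y, z, yd, zd, th, thd = s[0], s[1], s[2], s[3], s[4], s[5]

    a1y, a1z, a1t, _ = accels(y, z, yd, zd, th, thd, f_py, f_pz, f_ball,
                              m, l, g, c, m_ee, b_ee, clamped)
    k1 = (yd, zd, a1y, a1z, thd, a1t)

    h = 0.5 * dt
    a2y, a2z, a2t, _ = accels(y + h * k1[0], z + h * k1[1],
                              yd + h * k1[2], zd + h * k1[3],
                              th + h * k1[4], thd + h * k1[5],
                              f_py, f_pz, f_ball, m, l, g, c, m_ee, b_ee, clamped)
    k2 = (yd + h * k1[2], zd + h * k1[3], a2y, a2z, thd + h * k1[5], a2t)

    a3y, a3z, a3t, _ = accels(y + h * k2[0], z + h * k2[1],
                              yd + h * k2[2], zd + h * k2[3],
                              th + h * k2[4], thd + h * k2[5],
                              f_py, f_pz, f_ball, m, l, g, c, m_ee, b_ee, clamped)
    k3 = (yd + h * k2[2], zd + h * k2[3], a3y, a3z, thd + h * k2[5], a3t)

    a4y, a4z, a4t, _ = accels(y + dt * k3[0], z + dt * k3[1],
                              yd + dt * k3[2], zd + dt * k3[3],
                              th + dt * k3[4], thd + dt * k3[5],
                              f_py, f_pz, f_ball, m, l, g, c, m_ee, b_ee, clamped)
    k4 = (yd + dt * k3[2], zd + dt * k3[3], a4y, a4z, thd + dt * k3[5], a4t)

    w = dt / 6.0
    out[0] = y + w * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    out[1] = z + w * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    out[2] = yd + w * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    out[3] = zd + w * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    out[4] = th + w * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    out[5] = thd + w * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
    return out


@njit(cache=True)
def simulate_clamped(th0, thd0, n, dt, m, l, g, c):
    """Free swing with the pivot clamped; returns the theta trace (n+1 samples)."""
    th = np.empty(n + 1)
    s = np.zeros(6)
    s[4] = th0
    s[5] = thd0
    th[0] = th0
    for i in range(n):
        s = rk4_step(s, 0.0, 0.0, 0.0, dt, m, l, g, c, 1.0, 0.0, True)
        th[i + 1] = s[4]
    return th


# ---------------------------------------------------------------------------
# closed-loop integration spans (between controller updates)
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_span(s, i0, n, dt,
             ref_y, ref_yd, delay_steps,
             hp, hd, zp, zdamp, z_home, slack, noise,
             assist_mode, assist_f, assist_point,
             hg_y, hg_yd, hg_p, hg_d, hg_lim,
             m, l, g, c, m_ee, b_ee,
             log_y, log_z, log_yd, log_zd, log_th, log_thd,
             log_fhy, log_fhz, log_fay, log_fry, log_frz):
    """Integrate ``n`` sim steps with per-step hand PD and the assist force.

    The hand force tracks the (delayed) intent reference at the simulation
    rate.  ``assist_mode`` 0 holds ``assist_f`` constant for the span (MPC
    zero-order hold / no assistance); mode 1 evaluates the haptic-guidance
    PD against the frozen reference arrays ``hg_y``/``hg_yd`` at every step,
    clamped to ``hg_lim``.  Log arrays are filled at indices
    ``i0 .. i0+n-1`` with the pre-step state and the forces applied over
    that step.  Returns the updated state vector.
    """
    for i in range(i0, i0 + n):
        j = i - delay_steps
        if j < 0:
            j = 0
        e = ref_y[j] - s[0]
        ed = ref_yd[j] - s[2]
        fhy = slack * (hp * e + hd * ed + noise[i])
        fhz = zp * (z_home - s[1]) - zdamp * s[3]

        if assist_mode == 1:
            af = hg_p * (hg_y[i] - s[0]) + hg_d * (hg_yd[i] - s[2])
            if af > hg_lim:
                af = hg_lim
            elif af < -hg_lim:
                af = -hg_lim
        else:
            af = assist_f

        f_py = fhy
        f_ball = 0.0
        if assist_point == 1:
            f_py += af
        elif assist_point == 2:
            f_ball = af

        _, _, _, f_rod = accels(s[0], s[1], s[2], s[3], s[4], s[5],
                                f_py, fhz, f_ball, m, l, g, c, m_ee, b_ee, False)
        sth = np.sin(s[4])
        cth = np.cos(s[4])

        log_y[i] = s[0]
        log_z[i] = s[1]
        log_yd[i] = s[2]
        log_zd[i] = s[3]
        log_th[i] = s[4]
        log_thd[i] = s[5]
        log_fhy[i] = fhy
        log_fhz[i] = fhz
        log_fay[i] = af
        log_fry[i] = f_rod * sth
        log_frz[i] = -f_rod * cth

        s = rk4_step(s, f_py, fhz, f_ball, dt, m, l, g, c, m_ee, b_ee, False)
    return s


@njit(cache=True)
def run_transfer_span(s, i0, n, dt,
                      ke, kc, kcd, fmax, zp, zdamp, z_home, noise,
                      m, l, g, c, m_ee, b_ee,
                      log_y, log_z, log_yd, log_zd, log_th, log_thd,
                      log_fhy, log_fhz, log_fay, log_fry, log_frz):
    """Transfer (inversion) test: energy-pumping hand force, no assistance.

    The surrogate pumps mechanical energy toward the inverted-equilibrium
    level with the standard pivot-driven swing-up law
    u = -ke (E* - E) sign(th_dot cos th) (swing power is
    -m l y_ddot th_dot cos th, so the pivot must push against the sign
    term to feed energy in), plus a weak workspace-centering PD; capped at
    ``fmax``.  From rest the sign term is zero, so a fixed-direction kick
    starts the swing.
    """
    e_target = m * g * l
    for i in range(i0, i0 + n):
        en = 0.5 * m * l * l * s[5] * s[5] - m * g * l * np.cos(s[4])
        sgn = s[5] * np.cos(s[4])
        if sgn > 1e-3:
            sw = 1.0
        elif sgn < -1e-3:
            sw = -1.0
        elif en < e_target:
            sw = -1.0  # startup kick from rest
        else:
            sw = 0.0
        u = -ke * (e_target - en) * sw - kc * s[0] - kcd * s[2] + noise[i]
        if u > fmax:
            u = fmax
        elif u < -fmax:
            u = -fmax
        fhz = zp * (z_home - s[1]) - zdamp * s[3]

        _, _, _, f_rod = accels(s[0], s[1], s[2], s[3], s[4], s[5],
                                u, fhz, 0.0, m, l, g, c, m_ee, b_ee, False)
        log_y[i] = s[0]
        log_z[i] = s[1]
        log_yd[i] = s[2]
        log_zd[i] = s[3]
        log_th[i] = s[4]
        log_thd[i] = s[5]
        log_fhy[i] = u
        log_fhz[i] = fhz
        log_fay[i] = 0.0
        log_fry[i] = f_rod * np.sin(s[4])
        log_frz[i] = -f_rod * np.cos(s[4])

        s = rk4_step(s, u, fhz, 0.0, dt, m, l, g, c, m_ee, b_ee, False)
    return s


# ---------------------------------------------------------------------------
# MPC planning model (y-axis subsystem) and Gauss-Newton solver
# ---------------------------------------------------------------------------


@njit(cache=True)
def _plan_deriv(y, yd, th, thd, f, at_ball, m, l, g, c, m_ee, b_ee):
    """Planning-model derivatives: free pivot in y, z held (z̈ = 0), no hand force."""
    s = np.sin(th)
    ct = np.cos(th)
    if at_ball:
        f_py = 0.0
        f_ball = f
    else:
        f_py = f
        f_ball = 0.0
    base = m * (g * ct + l * thd * thd)
    ydd = (f_py - b_ee * yd + s * base + f_ball * s * s) / (m_ee + m * s * s)
    thdd = (-(g * s + ydd * ct) / l
            - c / (m * l * l) * thd
            + f_ball * ct / (m * l))
    return yd, ydd, thd, thdd


@njit(cache=True)
def plan_rollout(x0, forces, dt, at_ball, m, l, g, c, m_ee, b_ee):
    """RK4 rollout of the planning model; x = [y, yd, th, thd], shape (N+1, 4)."""
    n = forces.shape[0]
    xs = np.empty((n + 1, 4))
    xs[0] = x0
    y, yd, th, thd = x0[0], x0[1], x0[2], x0[3]
    for k in range(n):
        f = forces[k]
        d1 = _plan_deriv(y, yd, th, thd, f, at_ball, m, l, g, c, m_ee, b_ee)
        h = 0.5 * dt
        d2 = _plan_deriv(y + h * d1[0], yd + h * d1[1], th + h * d1[2],
                         thd + h * d1[3], f, at_ball, m, l, g, c, m_ee, b_ee)
        d3 = _plan_deriv(y + h * d2[0], yd + h * d2[1], th + h * d2[2],
                         thd + h * d2[3], f, at_ball, m, l, g, c, m_ee, b_ee)
        d4 = _plan_deriv(y + dt * d3[0], yd + dt * d3[1], th + dt * d3[2],
                         thd + dt * d3[3], f, at_ball, m, l, g, c, m_ee, b_ee)
        w = dt / 6.0
        y += w * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        yd += w * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        th += w * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        thd += w * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])
        xs[k + 1, 0] = y
        xs[k + 1, 1] = yd
        xs[k + 1, 2] = th
        xs[k + 1, 3] = thd
    return xs


@njit(cache=True)
def mpc_residuals(x0, forces, dt, at_ball, m, l, g, c, m_ee, b_ee,
                  target_y, sq_wd, sq_wspeed, sq_wf):
    """Weighted residual vector of the shooting problem.

    Residuals per horizon step k = 1..N: sqrt(w_dist) * (ball_y - target_y),
    sqrt(w_speed) * ball_vy, sqrt(w_speed) * ball_vz, and per decision step
    sqrt(w_F(k)) * F_k.  Squared 2-norm of this vector equals the MPC cost.
    """
    n = forces.shape[0]
    xs = plan_rollout(x0, forces, dt, at_ball, m, l, g, c, m_ee, b_ee)
    r = np.empty(4 * n)
    for k in range(1, n + 1):
        y, yd, th, thd = xs[k, 0], xs[k, 1], xs[k, 2], xs[k, 3]
        s = np.sin(th)
        ct = np.cos(th)
        r[4 * (k - 1) + 0] = sq_wd[k - 1] * (y + l * s - target_y)
        r[4 * (k - 1) + 1] = sq_wspeed * (yd + l * thd * ct)
        r[4 * (k - 1) + 2] = sq_wspeed * (l * thd * s)
        r[4 * (k - 1) + 3] = sq_wf[k - 1] * forces[k - 1]
    return r


@njit(cache=True)
def mpc_solve(x0, f_init, dt, at_ball, m, l, g, c, m_ee, b_ee,
              target_y, sq_wd, sq_wspeed, sq_wf,
              f_limit, iters, reg):
    """Projected Levenberg-Marquardt on the single-shooting problem.

    Fixed outer-iteration budget; finite-difference Jacobian.  The damping
    parameter starts at ``reg`` (which also keeps the normal equations well
    posed when the force weight vanishes at impact) and adapts: a step that
    increases the cost is retried with ten-fold damping, an accepted step
    relaxes it.  Forces are clipped to the box constraint after every
    update.  Deterministic throughout.  Returns (forces, cost).
    """
    n = f_init.shape[0]
    forces = np.empty(n)
    for j in range(n):
        f = f_init[j]
        if f > f_limit:
            f = f_limit
        elif f < -f_limit:
            f = -f_limit
        forces[j] = f

    h = 1e-5
    lam = reg
    r = mpc_residuals(x0, forces, dt, at_ball, m, l, g, c, m_ee, b_ee,
                      target_y, sq_wd, sq_wspeed, sq_wf)
    nr = r.shape[0]
    cost = 0.0
    for i in range(nr):
        cost += r[i] * r[i]

    for _ in range(iters):
        jac = np.empty((nr, n))
        for j in range(n):
            fp = forces.copy()
            fp[j] += h
            rp = mpc_residuals(x0, fp, dt, at_ball, m, l, g, c, m_ee, b_ee,
                               target_y, sq_wd, sq_wspeed, sq_wf)
            for i in range(nr):
                jac[i, j] = (rp[i] - r[i]) / h
        jtj = jac.T @ jac
        b = -(jac.T @ r)

        for _ in range(6):
            a = jtj + lam * np.eye(n)
            df = np.linalg.solve(a, b)
            trial = np.empty(n)
            for j in range(n):
                f = forces[j] + df[j]
                if f > f_limit:
                    f = f_limit
                elif f < -f_limit:
                    f = -f_limit
                trial[j] = f
            rt = mpc_residuals(x0, trial, dt, at_ball, m, l, g, c, m_ee,
                               b_ee, target_y, sq_wd, sq_wspeed, sq_wf)
            ct = 0.0
            for i in range(nr):
                ct += rt[i] * rt[i]
            if ct < cost:
                forces = trial
                r = rt
                cost = ct
                lam = max(lam * 0.25, reg)
                break
            lam *= 10.0

    return forces, cost
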