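"""Numba kernels for the coupled neural/hemodynamic system.

State layout per simulation: 15 values — z[0:3] neural states,
s[3:6] vasodilatory signal, f[6:9] blood inflow, v[9:12] venous volume,
q[12:15] deoxyhemoglobin content. Inputs u are piecewise constant on the
microtime grid and held fixed across Runge-Kutta substeps.

Status convention: a nonnegative status is the microtime index at which
integration left the admissible region (|z| beyond bound, or a log
hemodynamic state outside its band); STATUS_OK (-1) means the trajectory
stayed admissible.

Free-parameter layout (shared with dcm.py): parallel arrays kind/ii/jj/mm
map each theta entry onto the parameter set —
kind 0: A off-diagonal [ii, jj] (Hz)
kind 1: a_logscale diagonal [ii]
kind 2: B matrix of modulator mm, entry [ii, jj] (Hz)
kind 3: C entry [ii] (Hz)
kind 4: epsilon log-deviation of region ii
kind 5: tau log-deviation of region ii

The inner loops are written allocation-free on purpose: model inversion
evaluates these kernels tens of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = -1

K_A_OFF = 0
K_A_DIAG = 1
K_B = 2
K_C = 3
K_EPS = 4
K_TAU = 5

METHOD_RK4 = 0
METHOD_EULER = 1


#: admissibility bound on the log hemodynamic states (flow/volume/dHb
#: excursions beyond e^±8 are treated as model breakdown)
LOG_STATE_BOUND = 8.0


@njit(cache=True, error_model="numpy")
def _deriv15(st, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, out):
    """Time derivative of the full 15-state.

    Flow, volume and deoxyhemoglobin are integrated as logarithms
    (st[6:15] = ln f, ln v, ln q), which keeps them positive by
    construction; returns False once a log state leaves the admissible
    band.
    """
    n_mod = bstack.shape[0]
    for i in range(3):
        acc = c[i] * u_row[0]
        for j in range(3):
            m_ij = a_eff[i, j]
            for k in range(n_mod):
                uk = u_row[k]
                if uk != 0.0:
                    m_ij += uk * bstack[k, i, j]
            acc += m_ij * st[j]
        out[i] = acc
    ok = True
    for r in range(3):
        s = st[3 + r]
        xf = st[6 + r]
        xv = st[9 + r]
        xq = st[12 + r]
        if abs(xf) > LOG_STATE_BOUND or abs(xv) > LOG_STATE_BOUND or abs(xq) > LOG_STATE_BOUND:
            ok = False
            xf = min(max(xf, -LOG_STATE_BOUND), LOG_STATE_BOUND)
            xv = min(max(xv, -LOG_STATE_BOUND), LOG_STATE_BOUND)
            xq = min(max(xq, -LOG_STATE_BOUND), LOG_STATE_BOUND)
        f = np.exp(xf)
        v = np.exp(xv)
        fv = np.exp(xv * inv_alpha)          # v^(1/alpha)
        extraction = (1.0 - (1.0 - e0) ** (1.0 / f)) / e0
        out[3 + r] = eps3[r] * st[r] - kappa * s - gamma * (f - 1.0)
        out[6 + r] = s / f
        out[9 + r] = (f - fv) / (tau3[r] * v)
        out[12 + r] = (f * extraction * np.exp(-xq) - fv / v) / tau3[r]
    return ok


@njit(cache=True, error_model="numpy")
def _step15(st, u_row, dt, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0,
            method, d1, d2, d3, d4, tmp, lo, hi):
    """Advance state indices [lo, hi) by one step in place; returns admissibility."""
    if method == METHOD_EULER:
        ok = _deriv15(st, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, d1)
        for i in range(lo, hi):
            st[i] += dt * d1[i]
        return ok
    ok1 = _deriv15(st, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, d1)
    for i in range(15):
        tmp[i] = st[i]
    for i in range(lo, hi):
        tmp[i] = st[i] + 0.5 * dt * d1[i]
    ok2 = _deriv15(tmp, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, d2)
    for i in range(lo, hi):
        tmp[i] = st[i] + 0.5 * dt * d2[i]
    ok3 = _deriv15(tmp, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, d3)
    for i in range(lo, hi):
        tmp[i] = st[i] + dt * d3[i]
    ok4 = _deriv15(tmp, u_row, a_eff, bstack, c, eps3, tau3, kappa, gamma, inv_alpha, e0, d4)
    for i in range(lo, hi):
        st[i] += dt / 6.0 * (d1[i] + 2.0 * d2[i] + 2.0 * d3[i] + d4[i])
    return ok1 and ok2 and ok3 and ok4


@njit(cache=True, error_model="numpy")
def neural_trajectory(a_eff, bstack, c, u, dt, z0, method, bound):
    """Integrate the bilinear neural ODE alone on the microtime grid.

    Returns (traj, status): traj[(n_micro, 3)] holds the state at the
    *end* of each microtime step; traj[k] ~ z((k+1) dt) from z0 at t=0.
    """
    n = u.shape[0]
    traj = np.empty((n, 3))
    st = np.zeros(15)          # log hemo states rest at 0
    for r in range(3):
        st[r] = z0[r]
    eps3 = np.zeros(3)
    tau3 = np.ones(3)
    d1 = np.empty(15); d2 = np.empty(15); d3 = np.empty(15); d4 = np.empty(15); tmp = np.empty(15)
    status = STATUS_OK
    for k in range(n):
        _step15(st, u[k], dt, a_eff, bstack, c, eps3, tau3, 0.64, 0.32, 1.0, 0.4,
                method, d1, d2, d3, d4, tmp, 0, 3)
        for i in range(3):
            if not np.isfinite(st[i]) or abs(st[i]) > bound:
                status = k
        if status != STATUS_OK:
            for kk in range(k, n):
                for i in range(3):
                    traj[kk, i] = np.nan
            return traj, status
        for i in range(3):
            traj[k, i] = st[i]
    return traj, status


@njit(cache=True, error_model="numpy")
def hemo_trajectory(z_traj, dt, eps3, tau3, kappa, gamma, alpha, e0, v0, k1c, k2c, k3c, method):
    """Balloon-model BOLD driven by a prescribed neural trajectory.

    The neural input over step k is z_traj[k] (piecewise constant).
    Returns (y, states, status): y[(n, 3)] BOLD on the microtime grid,
    states[(n, 12)] = (s, f, v, q) per region.
    """
    n = z_traj.shape[0]
    inv_alpha = 1.0 / alpha
    y = np.empty((n, 3))
    states = np.empty((n, 12))
    st = np.zeros(15)          # log hemo states rest at 0
    a_eff = np.zeros((3, 3))
    bstack = np.zeros((0, 3, 3))
    cvec = np.zeros(3)
    u_row = np.zeros(1)
    d1 = np.empty(15); d2 = np.empty(15); d3 = np.empty(15); d4 = np.empty(15); tmp = np.empty(15)
    status = STATUS_OK
    for k in range(n):
        for r in range(3):
            st[r] = z_traj[k, r]  # neural states prescribed, not integrated
        ok = _step15(st, u_row, dt, a_eff, bstack, cvec, eps3, tau3, kappa, gamma,
                     inv_alpha, e0, method, d1, d2, d3, d4, tmp, 3, 15)
        if not ok:
            status = k
            for kk in range(k, n):
                for i in range(3):
                    y[kk, i] = np.nan
                for i in range(12):
                    states[kk, i] = np.nan
            return y, states, status
        for r in range(3):
            v = np.exp(st[9 + r])
            q = np.exp(st[12 + r])
            y[k, r] = v0 * (k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v))
            states[k, 0 + r] = st[3 + r]
            states[k, 3 + r] = np.exp(st[6 + r])
            states[k, 6 + r] = v
            states[k, 9 + r] = q
    return y, states, status


@njit(cache=True, error_model="numpy")
def bold_predict(a_eff, bstack, c, u, dt, eps3, tau3, kappa, gamma, alpha, e0, v0,
                 k1c, k2c, k3c, ratio, n_scans, method, bound):
    """Coupled neural+hemodynamic integration sampled at scan onsets.

    Scan k reads the state at microtime index k*ratio; output is
    mean-centered per region. Returns (y, status).
    """
    inv_alpha = 1.0 / alpha
    n_micro = u.shape[0]
    y = np.empty((n_scans, 3))
    st = np.zeros(15)          # log hemo states rest at 0
    d1 = np.empty(15); d2 = np.empty(15); d3 = np.empty(15); d4 = np.empty(15); tmp = np.empty(15)
    status = STATUS_OK
    scan = 0
    last_needed = (n_scans - 1) * ratio
    for k in range(n_micro):
        if scan < n_scans and k == scan * ratio:
            for r in range(3):
                v = np.exp(st[9 + r])
                q = np.exp(st[12 + r])
                y[scan, r] = v0 * (k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v))
            scan += 1
            if scan >= n_scans:
                break
        ok = _step15(st, u[k], dt, a_eff, bstack, c, eps3, tau3, kappa, gamma,
                     inv_alpha, e0, method, d1, d2, d3, d4, tmp, 0, 15)
        if not ok:
            status = k
        for r in range(3):
            if not np.isfinite(st[r]) or abs(st[r]) > bound:
                status = k
        if status != STATUS_OK:
            return y, status
        if k > last_needed:
            break
    for r in range(3):
        mu = 0.0
        for k in range(n_scans):
            mu += y[k, r]
        mu /= n_scans
        for k in range(n_scans):
            y[k, r] -= mu
    return y, status


@njit(cache=True, error_model="numpy")
def theta_to_mats(theta, kind, ii, jj, mm, a_base, b_base, c_base, eps_base, tau_base):
    """Map a free-parameter vector onto full parameter arrays.

    Base arrays carry the prior-mean/fixed values; theta entries are
    written (not added) at their indexed positions. ``a`` carries
    log-scale values on its diagonal; the returned a_eff has the diagonal
    converted to -0.5*exp(.) Hz.
    """
    a = a_base.copy()
    b = b_base.copy()
    c = c_base.copy()
    eps_ld = eps_base.copy()
    tau_ld = tau_base.copy()
    for p in range(theta.shape[0]):
        k = kind[p]
        if k == K_A_OFF:
            a[ii[p], jj[p]] = theta[p]
        elif k == K_A_DIAG:
            a[ii[p], ii[p]] = theta[p]
        elif k == K_B:
            b[mm[p], ii[p], jj[p]] = theta[p]
        elif k == K_C:
            c[ii[p]] = theta[p]
        elif k == K_EPS:
            eps_ld[ii[p]] = theta[p]
        elif k == K_TAU:
            tau_ld[ii[p]] = theta[p]
    for r in range(3):
        a[r, r] = -0.5 * np.exp(a[r, r])
    return a, b, c, eps_ld, tau_ld


@njit(cache=True, error_model="numpy")
def predict_from_theta(theta, kind, ii, jj, mm, a_base, b_base, c_base,
                       eps_base, tau_base, u, dt, ratio, n_scans,
                       kappa, gamma, tau0, alpha, e0, eps0, v0, k1c, k2c, k3c,
                       method, bound):
    """Predicted mean-centered BOLD for one free-parameter vector."""
    a_eff, b, c, eps_ld, tau_ld = theta_to_mats(
        theta, kind, ii, jj, mm, a_base, b_base, c_base, eps_base, tau_base)
    eps3 = eps0 * np.exp(eps_ld)
    tau3 = tau0 * np.exp(tau_ld)
    return bold_predict(a_eff, b, c, u, dt, eps3, tau3, kappa, gamma, alpha,
                        e0, v0, k1c, k2c, k3c, ratio, n_scans, method, bound)


@njit(cache=True, error_model="numpy")
def jacobian_fd(theta, kind, ii, jj, mm, a_base, b_base, c_base,
                eps_base, tau_base, u, dt, ratio, n_scans,
                kappa, gamma, tau0, alpha, e0, eps0, v0, k1c, k2c, k3c,
                method, bound, step):
    """Central finite-difference Jacobian of the stacked prediction.

    Returns (J, status): J[(n_scans*3, p)], rows stacked region-major
    (region r occupies rows r*n_scans..(r+1)*n_scans). status is the
    first failing perturbation's integration status.
    """
    p = theta.shape[0]
    jac = np.empty((n_scans * 3, p))
    status = STATUS_OK
    for a_idx in range(p):
        th = theta.copy()
        th[a_idx] = theta[a_idx] + step
        y_hi, s_hi = predict_from_theta(th, kind, ii, jj, mm, a_base, b_base, c_base,
                                        eps_base, tau_base, u, dt, ratio, n_scans,
                                        kappa, gamma, tau0, alpha, e0, eps0, v0,
                                        k1c, k2c, k3c, method, bound)
        th[a_idx] = theta[a_idx] - step
        y_lo, s_lo = predict_from_theta(th, kind, ii, jj, mm, a_base, b_base, c_base,
                                        eps_base, tau_base, u, dt, ratio, n_scans,
                                        kappa, gamma, tau0, alpha, e0, eps0, v0,
                                        k1c, k2c, k3c, method, bound)
        if s_hi != STATUS_OK or s_lo != STATUS_OK:
            status = max(s_hi, s_lo)
            return jac, status
        inv2h = 1.0 / (2.0 * step)
        for r in range(3):
            for k in range(n_scans):
                jac[r * n_scans + k, a_idx] = (y_hi[k, r] - y_lo[k, r]) * inv2h
    return jac, status
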