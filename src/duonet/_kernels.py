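"""Low-level numerical kernels (numba-compiled).

Everything here works on packed float64 vectors:

* parameters ``p`` — ``[b_e, b_g, k_e, k_g, f1..f4, K1..K4, n1..n4]``;
* condition ``c`` — ``[s_e, s_g, ici_alpha, d_ici]`` where ``s_e, s_g`` are
  the synthesis scales (zero inside a cycloheximide window — the Python
  wrappers split the timeline at window boundaries), ``ici_alpha`` the
  active-ERα fraction and ``d_ici`` the extra ERα loss rate.

The ODE integrator is an adaptive Dormand–Prince RK45; the deterministic
model is non-stiff for every parameter set inside the search box, and the
multi-start fitting loop needs on the order of a million short solves, so a
compiled explicit integrator is the appropriate tool.  A scipy ``solve_ivp``
route is cross-checked against it in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Hill regulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def hill_fold_scalar(x: float, f: float, K: float, n: float) -> float:
    """Fold-change Hill function ``(1 + f (x/K)^n) / (1 + (x/K)^n)``.

    Equals 1 at x = 0, tends to f as x grows, and lies strictly between
    min(1, f) and max(1, f) for finite positive x.
    """
    if x <= 0.0:
        return 1.0
    u = (x / K) ** n
    return (1.0 + f * u) / (1.0 + u)


@njit(cache=True)
def hill_fold_dx(x: float, f: float, K: float, n: float) -> float:
    """d/dx of the fold-change Hill function."""
    if x <= 0.0:
        if n == 1.0:
            return (f - 1.0) / K
        return 0.0
    u = (x / K) ** n
    denom = (1.0 + u) * (1.0 + u)
    return (f - 1.0) * n * u / (x * denom)


@njit(cache=True)
def hill_log_gain_scalar(x: float, f: float, K: float, n: float) -> float:
    """Logarithmic gain d log F / d log x of the Hill fold function."""
    u = (x / K) ** n
    return n * u * (f - 1.0) / ((1.0 + u) * (1.0 + f * u))


# ---------------------------------------------------------------------------
# Deterministic vector field
# ---------------------------------------------------------------------------


@njit(cache=True)
def rhs(y: np.ndarray, p: np.ndarray, c: np.ndarray, out: np.ndarray) -> None:
    e = y[0] if y[0] > 0.0 else 0.0
    g = y[1] if y[1] > 0.0 else 0.0
    ea = e * c[2]
    F1 = hill_fold_scalar(ea, p[4], p[8], p[12])
    F2 = hill_fold_scalar(g, p[5], p[9], p[13])
    F3 = hill_fold_scalar(ea, p[6], p[10], p[14])
    F4 = hill_fold_scalar(g, p[7], p[11], p[15])
    out[0] = c[0] * p[0] * F1 * F2 - (p[2] + c[3]) * y[0]
    out[1] = c[1] * p[1] * F3 * F4 - p[3] * y[1]


@njit(cache=True)
def jacobian(y: np.ndarray, p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at state y."""
    e = y[0] if y[0] > 0.0 else 0.0
    g = y[1] if y[1] > 0.0 else 0.0
    alpha = c[2]
    ea = e * alpha
    F1 = hill_fold_scalar(ea, p[4], p[8], p[12])
    F2 = hill_fold_scalar(g, p[5], p[9], p[13])
    F3 = hill_fold_scalar(ea, p[6], p[10], p[14])
    F4 = hill_fold_scalar(g, p[7], p[11], p[15])
    dF1 = hill_fold_dx(ea, p[4], p[8], p[12]) * alpha
    dF2 = hill_fold_dx(g, p[5], p[9], p[13])
    dF3 = hill_fold_dx(ea, p[6], p[10], p[14]) * alpha
    dF4 = hill_fold_dx(g, p[7], p[11], p[15])
    J = np.empty((2, 2))
    J[0, 0] = c[0] * p[0] * dF1 * F2 - (p[2] + c[3])
    J[0, 1] = c[0] * p[0] * F1 * dF2
    J[1, 0] = c[1] * p[1] * dF3 * F4
    J[1, 1] = c[1] * p[1] * F3 * dF4 - p[3]
    return J


# ---------------------------------------------------------------------------
# Adaptive Dormand–Prince RK45
# ---------------------------------------------------------------------------

# Butcher tableau (Dormand & Prince 5(4))
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
# 4th-order weights for the embedded error estimate
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def integrate_grid(
    t0: float,
    y0: np.ndarray,
    ts: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Integrate from (t0, y0), returning the state at each time in ts.

    ``ts`` must be non-decreasing with ``ts[0] >= t0``.  Returns an array of
    shape (len(ts), 2) filled with NaN on integrator failure.
    """
    nt = ts.shape[0]
    out = np.full((nt, 2), np.nan)
    y = y0.copy()
    t = t0
    k1 = np.empty(2)
    k2 = np.empty(2)
    k3 = np.empty(2)
    k4 = np.empty(2)
    k5 = np.empty(2)
    k6 = np.empty(2)
    k7 = np.empty(2)
    ytmp = np.empty(2)
    y5 = np.empty(2)
    rhs(y, p, c, k1)
    h = 0.05
    idx = 0
    # emit any output times equal to t0
    while idx < nt and ts[idx] <= t + 1e-12:
        out[idx, 0] = y[0]
        out[idx, 1] = y[1]
        idx += 1
    if idx >= nt:
        return out
    t_end = ts[nt - 1]
    max_steps = 2000000
    steps = 0
    while t < t_end:
        steps += 1
        if steps > max_steps:
            return np.full((nt, 2), np.nan)
        target = ts[idx]
        if h > target - t:
            h = target - t
        if h < 1e-14:
            h = 1e-14
        # stages
        for i in range(2):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        rhs(ytmp, p, c, k2)
        for i in range(2):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        rhs(ytmp, p, c, k3)
        for i in range(2):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs(ytmp, p, c, k4)
        for i in range(2):
            ytmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        rhs(ytmp, p, c, k5)
        for i in range(2):
            ytmp[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        rhs(ytmp, p, c, k6)
        for i in range(2):
            y5[i] = y[i] + h * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i])
        rhs(y5, p, c, k7)
        # error estimate
        err = 0.0
        for i in range(2):
            ei = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            err += (ei / sc) ** 2
        err = np.sqrt(err / 2.0)
        if err <= 1.0:
            t = t + h
            y[0] = y5[0] if y5[0] > 0.0 else 0.0
            y[1] = y5[1] if y5[1] > 0.0 else 0.0
            k1[0] = k7[0]
            k1[1] = k7[1]
            if y[0] != y5[0] or y[1] != y5[1]:
                rhs(y, p, c, k1)  # re-evaluate after clipping at zero
            while idx < nt and ts[idx] <= t + 1e-12:
                out[idx, 0] = y[0]
                out[idx, 1] = y[1]
                idx += 1
            if idx >= nt:
                return out
        # step-size update
        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * err ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        h = h * fac
        if h > 10.0:
            h = 10.0
    return out


# ---------------------------------------------------------------------------
# Steady states: damped Newton from a deterministic seed grid
# ---------------------------------------------------------------------------


@njit(cache=True)
def steady_state_scan(
    p: np.ndarray,
    c: np.ndarray,
    seeds: np.ndarray,
    box_hi: float,
    dedup_tol: float,
) -> np.ndarray:
    """Find non-negative fixed points inside [0, box_hi]^2.

    Newton iterations with analytic Jacobian are started from each row of
    ``seeds``; converged roots are deduplicated within ``dedup_tol`` per
    coordinate.  Returns an array (m, 2).
    """
    nseeds = seeds.shape[0]
    roots = np.empty((nseeds, 2))
    nroots = 0
    fy = np.empty(2)
    y = np.empty(2)
    for s in range(nseeds):
        if True:
            y[0] = seeds[s, 0]
            y[1] = seeds[s, 1]
            converged = False
            for _ in range(80):
                rhs(y, p, c, fy)
                if abs(fy[0]) < 1e-12 and abs(fy[1]) < 1e-12:
                    converged = True
                    break
                J = jacobian(y, p, c)
                det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
                if abs(det) < 1e-300:
                    break
                dx0 = (J[1, 1] * fy[0] - J[0, 1] * fy[1]) / det
                dx1 = (J[0, 0] * fy[1] - J[1, 0] * fy[0]) / det
                # damping: keep iterates inside a slightly enlarged box
                y[0] -= dx0
                y[1] -= dx1
                if y[0] < -0.5:
                    y[0] = -0.5
                elif y[0] > 2.0 * box_hi:
                    y[0] = 2.0 * box_hi
                if y[1] < -0.5:
                    y[1] = -0.5
                elif y[1] > 2.0 * box_hi:
                    y[1] = 2.0 * box_hi
            if not converged:
                continue
            if y[0] < -1e-9 or y[1] < -1e-9 or y[0] > box_hi or y[1] > box_hi:
                continue
            e_root = y[0] if y[0] > 0.0 else 0.0
            g_root = y[1] if y[1] > 0.0 else 0.0
            is_new = True
            for r in range(nroots):
                if abs(roots[r, 0] - e_root) < dedup_tol and abs(roots[r, 1] - g_root) < dedup_tol:
                    is_new = False
                    break
            if is_new:
                roots[nroots, 0] = e_root
                roots[nroots, 1] = g_root
                nroots += 1
    return roots[:nroots].copy()


# ---------------------------------------------------------------------------
# Exact stochastic simulation (Gillespie) of the four birth/death channels
# ---------------------------------------------------------------------------


@njit(cache=True)
def gillespie_counts(
    p: np.ndarray,
    c: np.ndarray,
    omega: float,
    e0: float,
    g0: float,
    t_end: float,
    sample_dt: float,
    seed: int,
) -> np.ndarray:
    """Simulate molecule counts, sampled on a regular time grid.

    Channels: ERα birth at rate ``omega * s_e * b_e * F1 * F2``, ERα death
    at ``(k_e + d_ici) * E``, GATA3 birth at ``omega * s_g * b_g * F3 * F4``
    and GATA3 death at ``k_g * G``.  Returns an array (n_samples, 2) of
    counts at times ``sample_dt, 2*sample_dt, ...``.
    """
    np.random.seed(seed)
    n_samples = int(t_end / sample_dt)
    out = np.empty((n_samples, 2))
    E = np.round(omega * e0)
    G = np.round(omega * g0)
    t = 0.0
    next_sample = sample_dt
    isamp = 0
    while isamp < n_samples:
        ea = (E / omega) * c[2]
        g = G / omega
        a1 = omega * c[0] * p[0] * hill_fold_scalar(ea, p[4], p[8], p[12]) * hill_fold_scalar(
            g, p[5], p[9], p[13]
        )
        a2 = (p[2] + c[3]) * E
        a3 = omega * c[1] * p[1] * hill_fold_scalar(ea, p[6], p[10], p[14]) * hill_fold_scalar(
            g, p[7], p[11], p[15]
        )
        a4 = p[3] * G
        a_tot = a1 + a2 + a3 + a4
        if a_tot <= 0.0:
            # absorbing state: fill remaining samples with the current counts
            while isamp < n_samples:
                out[isamp, 0] = E
                out[isamp, 1] = G
                isamp += 1
            break
        tau = -np.log(np.random.random()) / a_tot
        t_next = t + tau
        while isamp < n_samples and next_sample <= t_next:
            out[isamp, 0] = E
            out[isamp, 1] = G
            isamp += 1
            next_sample += sample_dt
        t = t_next
        r = np.random.random() * a_tot
        if r < a1:
            E += 1.0
        elif r < a1 + a2:
            E -= 1.0
        elif r < a1 + a2 + a3:
            G += 1.0
        else:
            G -= 1.0
    return out
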