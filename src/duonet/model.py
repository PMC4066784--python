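"""Deterministic two-gene ODE model with multiplicative Hill regulation.

The dimensionless model for normalised ERα (``e``) and GATA3 (``g``)
protein levels is

.. math::

    \\dot e = s_e\\, b_e\\, F_1(e_a)\\, F_2(g) - (k_e + d_{ici})\\, e, \\qquad
    \\dot g = s_g\\, b_g\\, F_3(e_a)\\, F_4(g) - k_g\\, g,

with fold-change Hill functions
``F_j(x) = (1 + f_j (x/K_j)^{n_j}) / (1 + (x/K_j)^{n_j})``, multiplicative
coupling of the two regulatory inputs of each gene, siRNA synthesis scales
``s_e, s_g``, active ERα ``e_a = alpha * e`` under ICI and an ICI-induced
extra loss ``d_ici``.  Concentrations are normalised so that the
unperturbed steady state is (1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .conditions import CONTROL, ExperimentalCondition
from .parameters import ModelParameters, normalize_to_wt  # noqa: F401  (re-export)
from .topology import RegulatoryTopology

__all__ = [
    "hill_fold",
    "log_gain",
    "derivatives",
    "normalize_to_wt",
    "Trajectory",
    "simulate",
    "steady_states",
    "stable_steady_state",
    "mrna_proxy",
    "simulate_experiment",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def hill_fold(x, f: float, K: float, n: float):
    """Fold-change Hill function ``(1 + f (x/K)^n) / (1 + (x/K)^n)``.

    Vectorised over ``x``.  Raises for non-positive or non-finite ``f``/``K``
    or cooperativity below 1.
    """
    f, K, n = float(f), float(K), float(n)
    if not (np.isfinite(f) and np.isfinite(K) and np.isfinite(n)):
        raise ValueError("Hill parameters must be finite")
    if f <= 0 or K <= 0:
        raise ValueError("fold f and half-saturation K must be > 0")
    if n < 1:
        raise ValueError("cooperativity n must be >= 1")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("regulator level x must be >= 0")
    if x_arr.ndim == 0:
        return _kernels.hill_fold_scalar(float(x_arr), f, K, n)
    u = (x_arr / K) ** n
    return (1.0 + f * u) / (1.0 + u)


def log_gain(f: float, K: float, n: float, x: float = 1.0) -> float:
    """Logarithmic gain ``d log F / d log x`` of a Hill fold function.

    Closed form ``n (x/K)^n (f - 1) / [(1 + (x/K)^n)(1 + f (x/K)^n)]``;
    its sign equals the sign of ``f - 1``, so it measures both the strength
    and the direction of the regulation at the operating point ``x``
    (``x = 1`` is the normalised wild-type level).
    """
    if x <= 0:
        raise ValueError("log gain is defined for x > 0")
    if f <= 0 or K <= 0:
        raise ValueError("fold f and half-saturation K must be > 0")
    return _kernels.hill_log_gain_scalar(float(x), float(f), float(K), float(n))


def derivatives(
    state,
    params: ModelParameters,
    condition: ExperimentalCondition = CONTROL,
    t: float = 0.0,
    topology: RegulatoryTopology | None = None,
):
    """Time derivatives (de/dt, dg/dt) at a state ``(e, g)``.

    ``t`` is used only to decide whether a cycloheximide window is active.
    If ``topology`` is given, the parameters are validated against it.
    """
    if topology is not None:
        params.validate_topology(topology)
    chx = condition.chx_window is not None and condition.chx_window[0] <= t < condition.chx_window[1]
    y = np.asarray(state, dtype=float)
    out = np.empty(2)
    _kernels.rhs(y, params.packed(), condition.packed(chx_active=chx), out)
    return out


@dataclass(frozen=True)
class Trajectory:
    """Time course of the network state."""

    t: np.ndarray
    e: np.ndarray
    g: np.ndarray

    def species(self, name: str) -> np.ndarray:
        if name == "era":
            return self.e
        if name == "gata3":
            return self.g
        raise KeyError(name)

    def to_frame(self, condition: str | None = None):
        """Tidy DataFrame with columns time_h, species, level (, condition)."""
        import pandas as pd

        frames = []
        for species, level in (("era", self.e), ("gata3", self.g)):
            df = pd.DataFrame({"time_h": self.t, "species": species, "level": level})
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        if condition is not None:
            out["condition"] = condition
        return out


def _segment_times(t_grid: np.ndarray, condition: ExperimentalCondition) -> list[tuple[float, float, bool]]:
    """Split [0, t_end] at cycloheximide window boundaries."""
    t0, t_end = 0.0, float(t_grid[-1])
    cuts = [t0]
    if condition.chx_window is not None:
        for b in condition.chx_window:
            if t0 < b < t_end:
                cuts.append(float(b))
    cuts.append(t_end)
    cuts = sorted(set(cuts))
    segments = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        chx = condition.chx_window is not None and condition.chx_window[0] <= mid < condition.chx_window[1]
        segments.append((a, b, chx))
    return segments


def simulate(
    params: ModelParameters,
    topology: RegulatoryTopology | None = None,
    condition: ExperimentalCondition = CONTROL,
    t_grid=None,
    initial_state=(1.0, 1.0),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "dopri",
) -> Trajectory:
    """Integrate the model over ``t_grid`` (hours, strictly increasing).

    ``initial_state`` is the state at t = 0; the grid may start later.
    Integration is restarted at every cycloheximide window boundary so the
    solution is continuous across the synthesis discontinuity.  The default
    integrator is the package's adaptive Dormand–Prince RK45 kernel;
    ``method="lsoda"`` routes through :func:`scipy.integrate.solve_ivp`
    instead (used as an independent cross-check).

    Raises
    ------
    RuntimeError
        If the integrator fails to reach the requested tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a 1-D array of times")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid times must be non-negative")
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (2,) or np.any(y0 < 0):
        raise ValueError("initial_state must be two non-negative levels")
    if topology is not None:
        params.validate_topology(topology)

    p = params.packed()
    out = np.empty((t_grid.size, 2))
    y = y0.copy()
    for a, b, chx in _segment_times(t_grid, condition):
        mask = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)
        # output times inside this segment, always ending at the boundary b
        ts = np.unique(np.concatenate([t_grid[mask], [b]]))
        ts = ts[ts >= a - 1e-12]
        c = condition.packed(chx_active=chx)
        if method == "dopri":
            seg = _kernels.integrate_grid(a, y, ts, p, c, rtol, atol)
        elif method == "lsoda":
            seg = _solve_ivp_segment(a, y, ts, p, c, rtol, atol)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(seg)):
            raise RuntimeError(
                f"ODE integration failed on [{a}, {b}] (tolerance rtol={rtol}); "
                "check parameter magnitudes"
            )
        for i, t in enumerate(ts):
            sel = np.isclose(t_grid, t, rtol=0.0, atol=1e-9)
            if np.any(sel):
                out[sel] = seg[i]
        y = seg[-1].copy()
    return Trajectory(t=t_grid, e=out[:, 0].copy(), g=out[:, 1].copy())


def _solve_ivp_segment(a, y, ts, p, c, rtol, atol):
    from scipy.integrate import solve_ivp

    def fun(t, yy):
        out = np.empty(2)
        _kernels.rhs(yy, p, c, out)
        return out

    sol = solve_ivp(fun, (a, ts[-1]), y, t_eval=ts, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        return np.full((len(ts), 2), np.nan)
    return sol.y.T


def steady_states(
    params: ModelParameters,
    topology: RegulatoryTopology | None = None,
    condition: ExperimentalCondition = CONTROL,
    box_hi: float = 10.0,
    ngrid: int = 25,
    dedup_tol: float = 1e-6,
) -> list[tuple[np.ndarray, bool]]:
    """All non-negative fixed points with stability flags.

    A damped Newton search with analytic Jacobian is seeded on an
    ``ngrid x ngrid`` grid over ``[0, box_hi]^2``, plus a finer auxiliary
    grid over ``[0, 2]^2`` where the normalised dynamics concentrate (fixed
    points of interest sit near the unit operating point, and saddles
    between low and wild-type states would slip through a coarse grid).
    Converged roots are deduplicated within ``dedup_tol``; stability is
    decided by the eigenvalues of the Jacobian (stable iff both real parts
    are negative).

    Cycloheximide windows are ignored here: fixed points refer to the
    post-window (or window-free) vector field.
    """
    if topology is not None:
        params.validate_topology(topology)
    p = params.packed()
    c = condition.packed(chx_active=False)
    axes = [np.linspace(0.5 / ngrid, 1.0 - 0.5 / ngrid, ngrid) * box_hi]
    if box_hi > 2.0:
        axes.append(np.linspace(0.025, 1.975, 20))
    seeds = np.concatenate(
        [np.stack(np.meshgrid(ax, ax), axis=-1).reshape(-1, 2) for ax in axes]
    )
    roots = _kernels.steady_state_scan(p, c, seeds, float(box_hi), float(dedup_tol))
    if roots.shape[0] == 0:
        raise RuntimeError(
            f"no fixed point found in [0, {box_hi}]^2; enlarge the bounding box"
        )
    out = []
    for root in roots:
        J = _kernels.jacobian(root, p, c)
        eig = np.linalg.eigvals(J)
        out.append((root.copy(), bool(np.all(eig.real < 0))))
    # deterministic ordering: by e then g
    out.sort(key=lambda item: (item[0][0], item[0][1]))
    return out


def stable_steady_state(
    params: ModelParameters,
    condition: ExperimentalCondition = CONTROL,
    **kwargs,
) -> np.ndarray:
    """The unique stable fixed point; raises if there is not exactly one."""
    fps = steady_states(params, condition=condition, **kwargs)
    stable = [fp for fp, ok in fps if ok]
    if len(stable) != 1:
        raise RuntimeError(f"expected one stable fixed point, found {len(stable)}")
    return stable[0]


def mrna_proxy(
    params: ModelParameters,
    state,
    condition: ExperimentalCondition = CONTROL,
    normalize: bool = True,
) -> float:
    """ERα transcription-rate readout ``b_e F_1(e_a) F_2(g)``.

    The model has no explicit mRNA variable; assuming mRNA equilibrates
    quickly, its steady-state level is proportional to the transcriptional
    production term.  With ``normalize=True`` the value is divided by the
    unperturbed wild-type production ``b_e F_1(1) F_2(1)``, so the proxy is
    1 in the absence of perturbation.
    """
    e, g = float(state[0]), float(state[1])
    ea = e * condition.ici_activity_factor
    F1 = _kernels.hill_fold_scalar(ea, params.f[0], params.K[0], params.n[0])
    F2 = _kernels.hill_fold_scalar(g, params.f[1], params.K[1], params.n[1])
    value = params.b_e * F1 * F2
    if not normalize:
        return value
    F1w = _kernels.hill_fold_scalar(1.0, params.f[0], params.K[0], params.n[0])
    F2w = _kernels.hill_fold_scalar(1.0, params.f[1], params.K[1], params.n[1])
    return value / (params.b_e * F1w * F2w)


def simulate_experiment(
    params: ModelParameters,
    condition: ExperimentalCondition,
    depletion_times,
    recovery_times,
    depletion_duration: float = 48.0,
    chx_duration: float = 15.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Model depletion and recovery read-outs for one siRNA condition.

    Protocol: siRNA from t = 0 starting at the wild-type state (1, 1);
    after ``depletion_duration`` hours a cycloheximide block of
    ``chx_duration`` hours (synthesis off, exact exponential decay);
    recovery is then monitored with the siRNA still present, with
    ``recovery_times`` measured from the washout.

    Returns ``(depletion_levels, recovery_levels)`` as arrays of shape
    (n_times, 2).
    """
    depletion_times = np.asarray(depletion_times, dtype=float)
    recovery_times = np.asarray(recovery_times, dtype=float)
    p = params.packed()
    c = condition.packed(chx_active=False)

    dep_grid = np.unique(np.concatenate([depletion_times, [depletion_duration]]))
    dep = _kernels.integrate_grid(0.0, np.array([1.0, 1.0]), dep_grid, p, c, rtol, atol)
    if not np.all(np.isfinite(dep)):
        raise RuntimeError("ODE integration failed during the depletion phase")
    dep_levels = np.empty((depletion_times.size, 2))
    for i, t in enumerate(depletion_times):
        dep_levels[i] = dep[np.searchsorted(dep_grid, t)]

    y_dep_end = dep[-1]
    # translation block: pure first-order decay, closed form
    decay = np.array(
        [
            np.exp(-(params.k_e + condition.ici_degradation_rate) * chx_duration),
            np.exp(-params.k_g * chx_duration),
        ]
    )
    y_washout = y_dep_end * decay

    rec_grid = np.unique(recovery_times)
    rec = _kernels.integrate_grid(0.0, y_washout, rec_grid, p, c, rtol, atol)
    if not np.all(np.isfinite(rec)):
        raise RuntimeError("ODE integration failed during the recovery phase")
    rec_levels = np.empty((recovery_times.size, 2))
    for i, t in enumerate(recovery_times):
        rec_levels[i] = rec[np.searchsorted(rec_grid, t)]
    return dep_levels, rec_levels
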