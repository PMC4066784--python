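"""Intrinsic and extrinsic expression noise of the two-gene network.

Intrinsic noise is computed with the Linear Noise Approximation (LNA): the
chemical master equation of four reaction channels (one birth and one death
channel per protein, birth propensities ``omega`` times the deterministic
synthesis terms) is linearised around the stable fixed point, and the
stationary covariance solves the continuous Lyapunov equation
``A C + C Aᵀ + D = 0``.  An exact Gillespie simulation of the same four
channels serves as the independent oracle for the LNA, and ensemble
propagation of lognormally perturbed rate parameters quantifies extrinsic
(parameter) noise.  Controlled link removal — fold set to 1 with the basal
rate of the regulated gene rescaled so the deterministic means are
untouched — isolates the effect of a regulatory link on noise from its
effect on means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .conditions import CONTROL, ExperimentalCondition
from .model import stable_steady_state, steady_states
from .parameters import ModelParameters
from .topology import RegulatoryTopology

__all__ = [
    "StochasticSystem",
    "NoiseSummary",
    "lna_noise",
    "gillespie",
    "GillespieResult",
    "remove_link_controlled",
    "extrinsic_noise",
    "calibrate_omega",
]


@dataclass(frozen=True)
class StochasticSystem:
    """Deterministic parameters plus a system size.

    ``omega`` converts a normalised concentration of 1.0 into a molecule
    count, setting the magnitude of intrinsic fluctuations; it is not
    measurable from the population-level data and is either calibrated to
    observed coefficients of variation (:func:`calibrate_omega`) or left at
    the default of 500 molecules per wild-type level.
    """

    params: ModelParameters
    topology: RegulatoryTopology | None = None
    omega: float = 500.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("system size omega must be > 0")
        if self.topology is not None:
            self.params.validate_topology(self.topology)

    def with_omega(self, omega: float) -> "StochasticSystem":
        return replace(self, omega=float(omega))


@dataclass(frozen=True)
class NoiseSummary:
    """Stationary means, CVs and covariance of the normalised levels."""

    mean_e: float
    mean_g: float
    cv_e: float
    cv_g: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        object.__setattr__(self, "covariance", cov)


def _drift_and_diffusion(system: StochasticSystem, condition: ExperimentalCondition):
    """Stable fixed point, Jacobian A and diffusion D (concentration units)."""
    fps = steady_states(system.params, condition=condition)
    stable = [fp for fp, ok in fps if ok]
    if len(stable) != 1:
        raise RuntimeError(
            f"LNA needs a unique stable fixed point; found {len(stable)} "
            f"stable of {len(fps)} total"
        )
    fp = stable[0]
    p = system.params.packed()
    c = condition.packed(chx_active=False)
    A = _kernels.jacobian(fp, p, c)
    if np.any(np.linalg.eigvals(A).real >= 0):
        raise RuntimeError("LNA invalid: Jacobian has a non-negative eigenvalue")
    # per-channel propensities per unit volume; birth = death at the fixed point
    e, g = fp
    ea = e * c[2]
    birth_e = c[0] * p[0] * _kernels.hill_fold_scalar(ea, p[4], p[8], p[12]) * _kernels.hill_fold_scalar(
        g, p[5], p[9], p[13]
    )
    birth_g = c[1] * p[1] * _kernels.hill_fold_scalar(ea, p[6], p[10], p[14]) * _kernels.hill_fold_scalar(
        g, p[7], p[11], p[15]
    )
    death_e = (p[2] + c[3]) * e
    death_g = p[3] * g
    D = np.diag([birth_e + death_e, birth_g + death_g]) / system.omega
    return fp, A, D


def lna_noise(system: StochasticSystem, condition: ExperimentalCondition = CONTROL) -> NoiseSummary:
    """Stationary intrinsic noise by the Linear Noise Approximation.

    For the all-null topology each species is an independent birth–death
    process with a Poisson stationary distribution, and the LNA covariance
    reduces exactly to ``var = mean / omega`` (``cv² = 1/(omega·mean)``).
    """
    from scipy.linalg import solve_continuous_lyapunov

    fp, A, D = _drift_and_diffusion(system, condition)
    C = solve_continuous_lyapunov(A, -D)
    C = 0.5 * (C + C.T)
    sd = np.sqrt(np.maximum(np.diag(C), 0.0))
    return NoiseSummary(
        mean_e=float(fp[0]),
        mean_g=float(fp[1]),
        cv_e=float(sd[0] / fp[0]),
        cv_g=float(sd[1] / fp[1]),
        covariance=C,
    )


@dataclass(frozen=True)
class GillespieResult:
    """Sampled molecule counts from an exact stochastic simulation."""

    counts: np.ndarray  # (n_samples, 2), sampled every sample_dt hours
    sample_dt: float
    omega: float
    burn_in_fraction: float = 0.2

    @property
    def stationary(self) -> np.ndarray:
        start = int(self.counts.shape[0] * self.burn_in_fraction)
        return self.counts[start:]

    def cv_estimates(self, n_batches: int = 50) -> dict[str, float]:
        """Stationary means and CVs with batch-mean standard errors.

        The post-burn-in samples are split into ``n_batches`` contiguous
        batches; the spread of per-batch CV estimates gives the Monte-Carlo
        standard error of the pooled CV.
        """
        data = self.stationary
        out: dict[str, float] = {}
        for i, sp in enumerate(("e", "g")):
            x = data[:, i]
            mean = x.mean()
            cv = x.std(ddof=1) / mean
            batches = np.array_split(x, n_batches)
            bcv = np.array([b.std(ddof=1) / b.mean() for b in batches])
            out[f"mean_{sp}"] = float(mean / self.omega)
            out[f"cv_{sp}"] = float(cv)
            out[f"se_cv_{sp}"] = float(bcv.std(ddof=1) / np.sqrt(n_batches))
        return out


def gillespie(
    system: StochasticSystem,
    condition: ExperimentalCondition = CONTROL,
    t_end: float = 4000.0,
    seed: int = 0,
    sample_dt: float = 0.5,
    initial_state=None,
) -> GillespieResult:
    """Exact stochastic simulation of the four birth/death channels.

    Starts from the deterministic stable fixed point unless
    ``initial_state`` (normalised levels) is given; identical seeds give
    identical trajectories.
    """
    if initial_state is None:
        initial_state = stable_steady_state(system.params, condition)
    e0, g0 = float(initial_state[0]), float(initial_state[1])
    counts = _kernels.gillespie_counts(
        system.params.packed(),
        condition.packed(chx_active=False),
        float(system.omega),
        e0,
        g0,
        float(t_end),
        float(sample_dt),
        int(seed) & 0x7FFFFFFF,
    )
    return GillespieResult(counts=counts, sample_dt=sample_dt, omega=system.omega)


_LINK_TO_GENE = {1: "era", 2: "era", 3: "gata3", 4: "gata3"}


def remove_link_controlled(system: StochasticSystem, j: int, mean_tol: float = 1e-6) -> StochasticSystem:
    """Remove link ``j`` while preserving the deterministic means.

    The link's fold is set to 1 and the basal synthesis rate of the gene it
    regulates (ERα for links 1–2, GATA3 for links 3–4) is rescaled so the
    unperturbed stationary state is unchanged, isolating the link's effect
    on fluctuations.  Raises if the adjusted system's stable mean deviates
    from the original by more than ``mean_tol``.
    """
    if j not in _LINK_TO_GENE:
        raise ValueError("link index must be in 1..4")
    fp = stable_steady_state(system.params, CONTROL)
    params = system.params.with_fold(j, 1.0)
    p = params
    F = [
        _kernels.hill_fold_scalar(x, p.f[i], p.K[i], p.n[i])
        for i, x in enumerate((fp[0], fp[1], fp[0], fp[1]))
    ]
    if _LINK_TO_GENE[j] == "era":
        params = params.replace(b_e=p.k_e * fp[0] / (F[0] * F[1]))
    else:
        params = params.replace(b_g=p.k_g * fp[1] / (F[2] * F[3]))
    new_fp = stable_steady_state(params, CONTROL)
    if np.max(np.abs(new_fp - fp)) > mean_tol:
        raise RuntimeError(
            f"controlled removal failed to preserve the means "
            f"(shift {np.max(np.abs(new_fp - fp)):.2e} > {mean_tol:g})"
        )
    topology = system.topology.with_sign(j, "0") if system.topology is not None else None
    return StochasticSystem(params=params, topology=topology, omega=system.omega)


def extrinsic_noise(
    system: StochasticSystem,
    condition: ExperimentalCondition = CONTROL,
    parameter_cv: float = 0.1,
    n_samples: int = 1000,
    seed: int = 0,
    vary: tuple[str, ...] = ("b_e", "b_g", "k_e", "k_g"),
    max_failure_fraction: float = 0.1,
) -> NoiseSummary:
    """Cell-to-cell variability from static parameter heterogeneity.

    Synthesis and degradation rates are drawn from independent mean-one
    lognormal distributions with coefficient of variation ``parameter_cv``
    around the fitted values; the deterministic steady state is solved for
    each draw and the ensemble statistics of the steady-state levels are
    returned.  No temporal parameter fluctuations are modelled.
    """
    if not 0.0 < parameter_cv <= 0.5:
        raise ValueError("parameter_cv must lie in (0, 0.5]")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(int(seed))
    sigma = np.sqrt(np.log1p(parameter_cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(n_samples, len(vary)))

    ref = stable_steady_state(system.params, condition)
    states = np.empty((n_samples, 2))
    failures = 0
    for s in range(n_samples):
        params = system.params
        updates = {name: getattr(params, name) * factors[s, i] for i, name in enumerate(vary)}
        params = params.replace(**updates)
        try:
            fps = steady_states(params, condition=condition)
        except RuntimeError:
            failures += 1
            states[s] = np.nan
            continue
        stable = [fp for fp, ok in fps if ok]
        if not stable:
            failures += 1
            states[s] = np.nan
            continue
        # under multistability follow the branch closest to the reference
        states[s] = min(stable, key=lambda fp: float(np.sum((fp - ref) ** 2)))
    if failures > max_failure_fraction * n_samples:
        raise RuntimeError(
            f"{failures}/{n_samples} parameter draws had no stable steady state; "
            "the ensemble is unreliable"
        )
    ok = np.all(np.isfinite(states), axis=1)
    sample = states[ok]
    mean = sample.mean(axis=0)
    cov = np.cov(sample.T)
    sd = np.sqrt(np.diag(cov))
    return NoiseSummary(
        mean_e=float(mean[0]),
        mean_g=float(mean[1]),
        cv_e=float(sd[0] / mean[0]),
        cv_g=float(sd[1] / mean[1]),
        covariance=cov,
    )


def calibrate_omega(
    system: StochasticSystem,
    target_cvs: tuple[float, float],
    condition: ExperimentalCondition = CONTROL,
    bounds: tuple[float, float] = (1.0, 1e9),
    mismatch_threshold: float = 0.5,
) -> float:
    """System size matching LNA CVs to measured control-condition CVs.

    LNA CVs scale exactly as ``1/sqrt(omega)``, so the least-squares match
    ``min_omega sum_i (cv_i(omega) - target_i)^2`` has the closed-form
    solution ``1/sqrt(omega) = sum c_i t_i / sum c_i^2`` with ``c_i`` the
    CVs at omega = 1.  For the all-null topology with a single target this
    reduces to the Poisson inversion ``omega = 1 / (cv² · mean)``.
    """
    t = np.asarray(target_cvs, dtype=float)
    if np.any(t <= 0):
        raise ValueError("target CVs must be positive")
    base = lna_noise(system.with_omega(1.0), condition)
    c = np.array([base.cv_e, base.cv_g])
    s = float(np.dot(c, t) / np.dot(c, c))
    omega = 1.0 / s**2
    if not bounds[0] <= omega <= bounds[1]:
        warnings.warn(
            f"calibrated omega {omega:.3g} outside bounds {bounds}; clipping",
            RuntimeWarning,
        )
        omega = float(np.clip(omega, *bounds))
    achieved = c / np.sqrt(omega)
    rel = np.max(np.abs(achieved - t) / t)
    if rel > mismatch_threshold:
        warnings.warn(
            f"omega calibration mismatch {rel:.1%} exceeds {mismatch_threshold:.0%}; "
            "the two target CVs are mutually inconsistent with intrinsic noise alone",
            RuntimeWarning,
        )
    return float(omega)
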