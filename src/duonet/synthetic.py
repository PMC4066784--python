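"""Synthetic perturbation data with the structure of the study's readouts.

The generator emulates western-blot-quantified protein time courses
(siRNA depletion over 0–48 h; recovery over ~0–10 h after a 15 h
cycloheximide block) and qPCR-style mRNA dose–response readouts, with
multiplicative lognormal measurement noise — densitometry and qPCR are
ratio-scale measurements, so relative error is the natural noise model.

The default ground truth is the consensus network (GATA3 → ERα activation,
ERα → GATA3 repression, positive GATA3 autoregulation, no ERα
autoregulation) with its two cross-regulatory fold changes solved
numerically so the knockdown steady states reproduce the study's
population-level shifts: ERα falls to ~50% of wild type under GATA3
depletion and GATA3 rises by ~15% under ERα depletion.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import CONTROL, ERA_KNOCKDOWN, GATA3_KNOCKDOWN, ExperimentalCondition
from .datasets import TimeCourseDataset
from .doseresponse import DEFAULT_DOSES, ici_dose_response
from .model import simulate_experiment, stable_steady_state
from .parameters import ModelParameters
from .topology import CONSENSUS_TOPOLOGY, RegulatoryTopology

__all__ = [
    "GeneratorConfig",
    "default_ground_truth",
    "generate_depletion_timecourses",
    "generate_recovery_timecourses",
    "generate_dose_response",
    "generate_study",
]

DEFAULT_DEPLETION_TIMES = (0.0, 12.0, 24.0, 36.0, 48.0)
DEFAULT_RECOVERY_TIMES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@functools.lru_cache(maxsize=8)
def default_ground_truth(
    era_under_gata3_kd: float = 0.5,
    gata3_under_era_kd: float = 1.15,
) -> tuple[RegulatoryTopology, ModelParameters]:
    """Calibrated consensus-network ground truth.

    Fixed shape choices (rationale in the package methods note): steep,
    near-threshold cross-regulation (n2 = n3 = 4, K2 = 1.2, K3 = 1.6) so
    the negative feedback loop is functional at the operating point;
    moderate positive GATA3 autoregulation (f4 = 3, K4 = 1, n4 = 2, local
    gain 0.5, monostable); no ERα autoregulation (f1 = 1); degradation
    rates for 4 h (ERα) and 8 h (GATA3) half-lives.  The cross-link folds
    (f2, f3) are then solved so that the 90%-efficiency knockdown steady
    states hit the target shifts exactly.
    """
    from scipy.optimize import root

    k_e = np.log(2.0) / 4.0
    k_g = np.log(2.0) / 8.0

    def build(f2: float, f3: float) -> ModelParameters:
        return ModelParameters(
            b_e=1.0,
            b_g=1.0,
            k_e=k_e,
            k_g=k_g,
            f=np.array([1.0, f2, f3, 3.0]),
            K=np.array([1.0, 1.2, 1.6, 1.0]),
            n=np.array([1.0, 4.0, 4.0, 2.0]),
        ).normalized()

    def residual(x):
        f2, f3 = np.exp(x[0]), 1.0 / (1.0 + np.exp(-x[1]))  # f2 > 0, f3 in (0, 1)
        params = build(f2, f3)
        e_kd = stable_steady_state(params, GATA3_KNOCKDOWN)[0]
        g_kd = stable_steady_state(params, ERA_KNOCKDOWN)[1]
        return [e_kd - era_under_gata3_kd, g_kd - gata3_under_era_kd]

    x0 = [np.log(4.0), np.log(0.47 / 0.53)]
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ground-truth calibration failed: {sol.message}")
    f2 = float(np.exp(sol.x[0]))
    f3 = float(1.0 / (1.0 + np.exp(-sol.x[1])))
    params = build(f2, f3)
    params.validate_topology(CONSENSUS_TOPOLOGY)
    return CONSENSUS_TOPOLOGY, params


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    The ground truth defaults to the calibrated consensus network; noise is
    mean-one multiplicative lognormal with the given coefficient of
    variation applied independently per replicate and observation
    (``noise_model="gaussian"`` switches to additive noise with the same
    relative scale).
    """

    topology: RegulatoryTopology = None  # type: ignore[assignment]
    params: ModelParameters = None  # type: ignore[assignment]
    conditions: tuple[ExperimentalCondition, ...] = (CONTROL, ERA_KNOCKDOWN, GATA3_KNOCKDOWN)
    depletion_times: tuple[float, ...] = DEFAULT_DEPLETION_TIMES
    recovery_times: tuple[float, ...] = DEFAULT_RECOVERY_TIMES
    depletion_duration: float = 48.0
    chx_duration: float = 15.0
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        if self.topology is None or self.params is None:
            topology, params = default_ground_truth()
            object.__setattr__(self, "topology", self.topology or topology)
            object.__setattr__(self, "params", self.params if self.params is not None else params)
        if not 0.0 <= self.noise_cv <= 0.5:
            raise ValueError("noise_cv must lie in [0, 0.5]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError("noise_model must be 'lognormal' or 'gaussian'")
        self.params.validate_topology(self.topology)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stream generator (independent of call order)."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


def _noisy_replicates(config: GeneratorConfig, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replicate observations of ``truth`` under the configured noise model."""
    shape = (config.n_replicates,) + truth.shape
    if config.noise_cv == 0.0:
        return np.broadcast_to(truth, shape).copy()
    if config.noise_model == "lognormal":
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)
        return truth * factors
    noisy = truth + rng.normal(scale=config.noise_cv, size=shape) * truth
    return np.maximum(noisy, 1e-6)


def _summarise(replicates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = replicates.mean(axis=0)
    if replicates.shape[0] > 1:
        sd = replicates.std(axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    return mean, sd


def _phase_datasets(config: GeneratorConfig, phase: str) -> list[TimeCourseDataset]:
    stream_base = 1 if phase == "depletion" else 2
    times = np.asarray(
        config.depletion_times if phase == "depletion" else config.recovery_times, dtype=float
    )
    out = []
    for i, condition in enumerate(config.conditions):
        dep, rec = simulate_experiment(
            config.params,
            condition,
            config.depletion_times,
            config.recovery_times,
            depletion_duration=config.depletion_duration,
            chx_duration=config.chx_duration,
        )
        truth = dep if phase == "depletion" else rec
        rng = config.rng(stream_base * 1000 + i)
        reps = _noisy_replicates(config, truth, rng)
        mean, sd = _summarise(reps)
        out.append(
            TimeCourseDataset.from_arrays(
                condition=condition,
                phase=phase,
                times=times,
                era_levels=mean[:, 0],
                gata3_levels=mean[:, 1],
                era_sds=sd[:, 0],
                gata3_sds=sd[:, 1],
                n_replicates=config.n_replicates,
            )
        )
    return out


def generate_depletion_timecourses(config: GeneratorConfig) -> list[TimeCourseDataset]:
    """siRNA depletion time courses from the wild-type state (1, 1).

    One dataset per condition, sampled at ``config.depletion_times``
    (default 0–48 h), reporting per-time replicate means and standard
    deviations.  Seed-reproducible; with ``noise_cv=0`` and one replicate
    the output equals the deterministic model trajectory exactly.
    """
    return _phase_datasets(config, "depletion")


def generate_recovery_timecourses(config: GeneratorConfig) -> list[TimeCourseDataset]:
    """Cycloheximide-chase recovery time courses.

    Protocol per condition: 48 h siRNA depletion, a 15 h translation block
    with the siRNA continued (protein decays exponentially), then recovery
    after washout — still under siRNA — sampled at ``config.recovery_times``
    measured from the washout.
    """
    return _phase_datasets(config, "recovery")


def generate_dose_response(
    config: GeneratorConfig,
    doses: Sequence[float] = DEFAULT_DOSES,
):
    """qPCR-style ICI dose–response table of the ERα mRNA proxy.

    Steady-state proxy levels per dose, with multiplicative noise applied
    per replicate and each replicate renormalised to its own dose-0 value
    (as fold-change readouts are).  Returns a DataFrame with columns
    ``dose_nM, mrna_proxy, sd``.
    """
    import pandas as pd

    curve = ici_dose_response(config.params, doses, topology=config.topology)
    rng = config.rng(3000)
    reps = _noisy_replicates(config, curve.levels, rng)
    reps = reps / reps[:, :1]
    mean, sd = _summarise(reps)
    return pd.DataFrame({"dose_nM": np.asarray(doses, float), "mrna_proxy": mean, "sd": sd})


def generate_study(config: GeneratorConfig) -> list[TimeCourseDataset]:
    """Depletion plus recovery datasets for all configured conditions."""
    return generate_depletion_timecourses(config) + generate_recovery_timecourses(config)
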