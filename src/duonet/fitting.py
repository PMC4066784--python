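"""Topology fitting: multi-start least squares on perturbation time courses.

The central objects follow the model/results convention of statistical
modelling packages:

* :class:`TopologyFit` — built from a list of time-course datasets and a
  candidate sign topology; owns the objective (standard-deviation-weighted
  sum of squared residuals between simulated and observed normalised
  levels) and the parameter space implied by the topology's signs.
* :class:`TopologyFitResults` — returned by :meth:`TopologyFit.fit`;
  carries the converged parameter sets of every optimisation start sorted
  by error, and exposes the downstream analyses (logarithmic gains,
  link-elimination error changes, ICI dose–response curves, summary table).

Null links are frozen at fold exactly 1, so nested topologies are genuine
sub-models.  Degradation rates are identified separately from the
cycloheximide decay between the 48 h depletion level and the recovery
starting level, and held fixed across topologies during model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kernels
from .datasets import SPECIES, TimeCourseDataset
from .doseresponse import DoseResponse, ici_dose_response
from .model import log_gain
from .parameters import ModelParameters, ParameterBounds
from .topology import RegulatoryTopology, Sign, autoregulation_topologies

__all__ = [
    "FitResult",
    "TopologyFit",
    "TopologyFitResults",
    "estimate_degradation_rates",
    "fit_topology",
    "rank_topologies",
    "link_elimination_error_change",
    "PENALTY_RESIDUAL",
]

#: residual value substituted for every observation when integration fails,
#: keeping the objective finite so the optimiser can back away
PENALTY_RESIDUAL = 1.0e3

SD_FLOOR_DEFAULT = 0.05


def estimate_degradation_rates(
    datasets: Sequence[TimeCourseDataset],
    chx_duration: float = 15.0,
) -> tuple[float, float]:
    """Estimate (k_e, k_g) from the cycloheximide decay.

    During the translation block each protein decays exponentially, so for
    every condition observed in both phases
    ``k = ln(level_depletion_end / level_recovery_start) / chx_duration``.
    Estimates are averaged over conditions; under a translation block the
    decay is independent of all regulatory parameters, which is what makes
    the rates identifiable separately from the network.
    """
    dep = {ds.condition.label: ds for ds in datasets if ds.phase == "depletion"}
    rec = {ds.condition.label: ds for ds in datasets if ds.phase == "recovery"}
    estimates: dict[str, list[float]] = {sp: [] for sp in SPECIES}
    for label, dep_ds in dep.items():
        rec_ds = rec.get(label)
        if rec_ds is None:
            continue
        for sp in SPECIES:
            t_d, lev_d, _ = dep_ds.series(sp)
            t_r, lev_r, _ = rec_ds.series(sp)
            if t_d.size == 0 or t_r.size == 0 or t_r[0] != 0.0:
                continue
            end_level = lev_d[np.argmax(t_d)]
            k = np.log(end_level / lev_r[0]) / chx_duration
            if k > 0:
                estimates[sp].append(float(k))
    if not estimates["era"] or not estimates["gata3"]:
        raise ValueError(
            "degradation rates need paired depletion/recovery datasets with a t=0 recovery point"
        )
    return float(np.mean(estimates["era"])), float(np.mean(estimates["gata3"]))


@dataclass(frozen=True)
class FitResult:
    """One converged optimisation start."""

    topology: RegulatoryTopology
    params: ModelParameters
    error: float
    x: np.ndarray
    converged: bool
    start_index: int


class TopologyFit:
    """Weighted least-squares fit of one sign topology to time courses.

    Parameters
    ----------
    datasets
        Depletion and/or recovery :class:`TimeCourseDataset` objects.
        Depletion phases are simulated from the wild-type state (1, 1);
        recovery phases from the post-cycloheximide level of the same
        condition, with the siRNA continued throughout.
    topology
        Candidate sign assignment.  Every non-null link contributes three
        free parameters (log fold, log half-saturation, cooperativity);
        null links are frozen at fold 1.
    k_e, k_g
        Degradation rates per hour.  Estimated from the cycloheximide decay
        (see :func:`estimate_degradation_rates`) when omitted.
    sd_floor
        Lower bound on the per-observation standard deviation used in the
        weights, guarding against vanishing replicate scatter.
    """

    def __init__(
        self,
        datasets: Sequence[TimeCourseDataset],
        topology: RegulatoryTopology,
        k_e: float | None = None,
        k_g: float | None = None,
        sd_floor: float = SD_FLOOR_DEFAULT,
        bounds: ParameterBounds = ParameterBounds(),
        depletion_duration: float = 48.0,
        chx_duration: float = 15.0,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> None:
        if not datasets:
            raise ValueError("at least one dataset is required")
        self.datasets = list(datasets)
        self.topology = topology
        self.sd_floor = float(sd_floor)
        self.bounds = bounds
        self.depletion_duration = float(depletion_duration)
        self.chx_duration = float(chx_duration)
        self.rtol, self.atol = float(rtol), float(atol)
        if k_e is None or k_g is None:
            k_e, k_g = estimate_degradation_rates(datasets, chx_duration)
        self.k_e, self.k_g = float(k_e), float(k_g)
        self._build_parameter_space()
        self._build_condition_cache()

    # ------------------------------------------------------------------
    # parameter space
    # ------------------------------------------------------------------
    def _build_parameter_space(self) -> None:
        names, lo, hi = [], [], []
        self._free_links = self.topology.free_links()
        for j in self._free_links:
            f_lo, f_hi = self.bounds.fold_bounds(self.topology.sign(j))
            names += [f"log_f{j}", f"log_K{j}", f"n{j}"]
            lo += [np.log(f_lo), np.log(self.bounds.K[0]), self.bounds.n[0]]
            hi += [np.log(f_hi), np.log(self.bounds.K[1]), self.bounds.n[1]]
        self.param_names = tuple(names)
        self.lower = np.asarray(lo)
        self.upper = np.asarray(hi)
        self.n_free = len(names)

    def build_params(self, x: np.ndarray) -> ModelParameters:
        """Unpack a free-parameter vector into normalised model parameters."""
        f = np.ones(4)
        K = np.ones(4)
        n = np.ones(4)
        for i, j in enumerate(self._free_links):
            f[j - 1] = np.exp(x[3 * i])
            K[j - 1] = np.exp(x[3 * i + 1])
            n[j - 1] = x[3 * i + 2]
        return ModelParameters(1.0, 1.0, self.k_e, self.k_g, f, K, n).normalized()

    def pack_params(self, params: ModelParameters) -> np.ndarray:
        """Project model parameters onto this topology's free vector.

        Values are clipped into the bounds (a fold of exactly 1 on a
        non-null link lands on the open boundary next to 1), which lets a
        nested sub-model's optimum seed a super-model's search.
        """
        x = np.empty(self.n_free)
        for i, j in enumerate(self._free_links):
            x[3 * i] = np.log(params.f[j - 1])
            x[3 * i + 1] = np.log(params.K[j - 1])
            x[3 * i + 2] = params.n[j - 1]
        return np.clip(x, self.lower, self.upper)

    # ------------------------------------------------------------------
    # data cache
    # ------------------------------------------------------------------
    def _build_condition_cache(self) -> None:
        groups: dict[str, dict] = {}
        for ds in self.datasets:
            entry = groups.setdefault(ds.condition.label, {"condition": ds.condition})
            if ds.phase in entry:
                raise ValueError(
                    f"duplicate {ds.phase} dataset for condition {ds.condition.label!r}"
                )
            entry[ds.phase] = ds
        self._entries = []
        n_obs = 0
        for label in sorted(groups):
            entry = groups[label]
            cond = entry["condition"]
            cache = {"condition": cond, "c": cond.packed(chx_active=False)}
            dep = entry.get("depletion")
            grid = [self.depletion_duration]
            if dep is not None:
                grid = np.concatenate([dep.unique_times(), grid])
            cache["dep_grid"] = np.unique(np.asarray(grid, dtype=float))
            for phase_key, ds in (("dep", dep), ("rec", entry.get("recovery"))):
                if ds is None:
                    cache[phase_key] = None
                    continue
                if phase_key == "rec":
                    cache["rec_grid"] = ds.unique_times()
                grid_arr = cache["dep_grid"] if phase_key == "dep" else cache["rec_grid"]
                obs = []
                for si, sp in enumerate(SPECIES):
                    t, lev, sd = ds.series(sp)
                    idx = np.searchsorted(grid_arr, t)
                    w = np.maximum(sd, self.sd_floor)
                    obs.append((idx, si, lev, w))
                    n_obs += t.size
                cache[phase_key] = obs
            self._entries.append(cache)
        self.n_obs = n_obs

    # ------------------------------------------------------------------
    # objective
    # ------------------------------------------------------------------
    def residuals(self, x: np.ndarray) -> np.ndarray:
        """Weighted residual vector at a free-parameter point ``x``."""
        params = self.build_params(x)
        return self._residuals_params(params)

    def _residuals_params(self, params: ModelParameters) -> np.ndarray:
        p = params.packed()
        out = np.empty(self.n_obs)
        pos = 0
        y0 = np.array([1.0, 1.0])
        for cache in self._entries:
            c = cache["c"]
            dep_needed = cache["dep"] is not None or cache["rec"] is not None
            dep = None
            if dep_needed:
                dep = _kernels.integrate_grid(0.0, y0, cache["dep_grid"], p, c, self.rtol, self.atol)
            if cache["dep"] is not None:
                pos = self._emit(out, pos, dep, cache["dep"])
            if cache["rec"] is not None:
                d_ici = cache["condition"].ici_degradation_rate
                decay = np.array(
                    [
                        np.exp(-(params.k_e + d_ici) * self.chx_duration),
                        np.exp(-params.k_g * self.chx_duration),
                    ]
                )
                if dep is None or not np.all(np.isfinite(dep)):
                    rec = np.full((cache["rec_grid"].size, 2), np.nan)
                else:
                    y_washout = dep[-1] * decay
                    rec = _kernels.integrate_grid(
                        0.0, y_washout, cache["rec_grid"], p, c, self.rtol, self.atol
                    )
                pos = self._emit(out, pos, rec, cache["rec"])
        return out

    @staticmethod
    def _emit(out, pos, sim, obs_list):
        for idx, si, lev, w in obs_list:
            vals = sim[idx, si]
            r = (vals - lev) / w
            bad = ~np.isfinite(r)
            if np.any(bad):
                r = np.where(bad, PENALTY_RESIDUAL, r)
            out[pos : pos + r.size] = r
            pos += r.size
        return pos

    def fit_error(self, params: ModelParameters | np.ndarray) -> float:
        """The fit error E: weighted sum of squared residuals."""
        if isinstance(params, ModelParameters):
            r = self._residuals_params(params)
        else:
            r = self.residuals(np.asarray(params, dtype=float))
        return float(np.dot(r, r))

    # ------------------------------------------------------------------
    # optimisation
    # ------------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 200,
        seed: int | None = None,
        extra_starts: Iterable[ModelParameters] | None = None,
        polish_top: int = 5,
        max_nfev: int = 400,
    ) -> "TopologyFitResults":
        """Multi-start bounded least squares.

        ``n_starts`` Latin-hypercube initial points (seeded, reproducible)
        are each refined by a trust-region-reflective local search; the
        best ``polish_top`` solutions get a second, tighter refinement.
        ``extra_starts`` may supply warm starts, e.g. the optimum of a
        nested sub-topology.
        """
        from scipy.optimize import least_squares
        from scipy.stats import qmc

        if seed is None:
            seed = 0
        starts: list[np.ndarray] = []
        if self.n_free > 0:
            sampler = qmc.LatinHypercube(d=self.n_free, seed=int(seed))
            unit = sampler.random(n_starts)
            starts = list(self.lower + unit * (self.upper - self.lower))
        else:
            starts = [np.empty(0)]
        for extra in extra_starts or ():
            starts.append(self.pack_params(extra))

        results: list[FitResult] = []
        for i, x0 in enumerate(starts):
            if self.n_free == 0:
                params = self.build_params(x0)
                results.append(
                    FitResult(self.topology, params, self.fit_error(params), x0, True, i)
                )
                continue
            sol = least_squares(
                self.residuals,
                x0,
                bounds=(self.lower, self.upper),
                method="trf",
                max_nfev=max_nfev,
            )
            results.append(
                FitResult(
                    self.topology,
                    self.build_params(sol.x),
                    float(2.0 * sol.cost),
                    sol.x,
                    bool(sol.success),
                    i,
                )
            )
        results = [r for r in results if r.converged]
        if not results:
            raise RuntimeError("no optimisation start converged")
        results.sort(key=lambda r: (r.error, r.start_index))

        if self.n_free > 0 and polish_top > 0:
            polished = []
            for r in results[:polish_top]:
                sol = least_squares(
                    self.residuals,
                    r.x,
                    bounds=(self.lower, self.upper),
                    method="trf",
                    max_nfev=4 * max_nfev,
                    ftol=1e-14,
                    xtol=1e-14,
                    gtol=1e-14,
                )
                polished.append(
                    FitResult(
                        self.topology,
                        self.build_params(sol.x),
                        float(2.0 * sol.cost),
                        sol.x,
                        True,
                        r.start_index,
                    )
                )
            results = polished + results[polish_top:]
            results.sort(key=lambda r: (r.error, r.start_index))
        return TopologyFitResults(self, results, n_starts=n_starts, seed=int(seed))


class TopologyFitResults:
    """Converged fits of one topology, sorted ascending by error."""

    def __init__(self, model: TopologyFit, results: Sequence[FitResult], n_starts: int, seed: int):
        self.model = model
        self.results = list(results)
        self.n_starts = n_starts
        self.seed = seed

    # -- basic access ----------------------------------------------------
    @property
    def topology(self) -> RegulatoryTopology:
        return self.model.topology

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def params(self) -> ModelParameters:
        return self.best.params

    @property
    def error(self) -> float:
        return self.best.error

    def top(self, k: int = 50) -> list[FitResult]:
        """The ``k`` best parameter sets (the default ensemble size used by
        the gain, elimination and dose–response analyses)."""
        return self.results[:k]

    # -- analyses --------------------------------------------------------
    def log_gains(self, j: int = 1, x: float = 1.0, k: int = 50) -> np.ndarray:
        """Logarithmic gain of link ``j`` at level ``x`` across the top fits.

        For j = 1 and x = 1 this is the strength of ERα autoregulation at
        the wild-type operating point.
        """
        return np.array(
            [log_gain(r.params.f[j - 1], r.params.K[j - 1], r.params.n[j - 1], x) for r in self.top(k)]
        )

    def eliminate_link(self, j: int, k: int = 50) -> np.ndarray:
        """Percentage error change after setting ``f_j = 1`` in the top fits."""
        return np.array(
            [link_elimination_error_change(self.model, r.params, j) for r in self.top(k)]
        )

    def dose_response(self, doses: Sequence[float], k: int = 50, **kwargs) -> list[DoseResponse]:
        """ICI dose–response curve of each of the top ``k`` parameter sets."""
        return [ici_dose_response(r.params, doses, **kwargs) for r in self.top(k)]

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Topology fit results",
            "====================",
            f"topology        {self.topology.to_string()}  ({self.topology.describe()})",
            f"observations    {self.model.n_obs}",
            f"free parameters {self.model.n_free}",
            f"starts          {self.n_starts} (seed {self.seed}), converged {len(self.results)}",
            f"degradation     k_e={self.model.k_e:.4f}/h  k_g={self.model.k_g:.4f}/h",
            f"best error E    {self.error:.6g}",
            "",
            "best parameters",
            "---------------",
        ]
        p = self.params
        lines.append(f"  b_e={p.b_e:.4g}  b_g={p.b_g:.4g}")
        for j in range(1, 5):
            sign = self.topology.sign(j).value
            lg = log_gain(p.f[j - 1], p.K[j - 1], p.n[j - 1], 1.0)
            lines.append(
                f"  link {j} [{sign}]  f={p.f[j - 1]:.4g}  K={p.K[j - 1]:.4g}  "
                f"n={p.n[j - 1]:.3g}  LG(1)={lg:+.4f}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay observed levels and the best-fit trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.params.packed()
        colors = {}
        for i, cache in enumerate(self.model._entries):
            colors[cache["condition"].label] = f"C{i}"
        for ds in self.model.datasets:
            color = colors[ds.condition.label]
            for sp, marker in (("era", "o"), ("gata3", "s")):
                t, lev, sd = ds.series(sp)
                offset = 0.0 if ds.phase == "depletion" else self.model.depletion_duration + self.model.chx_duration
                ax.errorbar(t + offset, lev, yerr=sd, fmt=marker, ms=4, color=color, alpha=0.6)
        for cache in self.model._entries:
            c = cache["c"]
            grid = np.linspace(0.0, self.model.depletion_duration, 100)
            sim = _kernels.integrate_grid(0.0, np.array([1.0, 1.0]), grid, p, c, 1e-8, 1e-10)
            label = cache["condition"].label
            ax.plot(grid, sim[:, 0], "-", color=colors[label], label=f"{label} ERα")
            ax.plot(grid, sim[:, 1], "--", color=colors[label], label=f"{label} GATA3")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalised level")
        ax.legend(fontsize=7)
        return ax


def link_elimination_error_change(
    model: TopologyFit,
    params: ModelParameters,
    j: int,
) -> float:
    """Percentage change in E after eliminating link ``j``.

    The link's fold is set to exactly 1 (shape parameters untouched), the
    wild-type normalisation is re-applied so the unperturbed steady state
    stays at (1, 1), and the error is recomputed on the same datasets:
    ``100 * (E_eliminated - E_fit) / E_fit``.

    Raises
    ------
    ZeroDivisionError
        If the reference error is exactly zero (report the absolute change
        ``model.fit_error(eliminated)`` instead).
    """
    e_fit = model.fit_error(params)
    eliminated = params.with_fold(j, 1.0).normalized()
    e_removed = model.fit_error(eliminated)
    if e_fit == 0.0:
        raise ZeroDivisionError(
            "fit error is exactly zero; the percentage change is undefined "
            f"(absolute eliminated error: {e_removed:g})"
        )
    return 100.0 * (e_removed - e_fit) / e_fit


def fit_topology(
    topology: RegulatoryTopology,
    datasets: Sequence[TimeCourseDataset],
    n_starts: int = 200,
    seed: int | None = None,
    **model_kwargs,
) -> TopologyFitResults:
    """Convenience wrapper: build a :class:`TopologyFit` and fit it."""
    return TopologyFit(datasets, topology, **model_kwargs).fit(n_starts=n_starts, seed=seed)


def rank_topologies(
    datasets: Sequence[TimeCourseDataset],
    topologies: Sequence[RegulatoryTopology] | None = None,
    n_starts: int = 200,
    seed: int | None = None,
    tolerance_factor: float = 2.0,
    **model_kwargs,
):
    """Fit a family of topologies and rank them by best error.

    By default the nine autoregulation variants (cross-links fixed to the
    experimentally determined signs) are fitted, each with its own seeded
    multi-start search but shared degradation rates.  A topology "captures
    the data" when its best error is within ``tolerance_factor`` of the
    global best.

    Returns
    -------
    leaderboard : pandas.DataFrame
        Columns ``topology, error, error_ratio, passes``, sorted by error.
    fits : dict[str, TopologyFitResults]
        Keyed by the topology's compact string.
    """
    import pandas as pd

    if topologies is None:
        topologies = autoregulation_topologies()
    if seed is None:
        seed = 0
    if "k_e" not in model_kwargs or "k_g" not in model_kwargs:
        k_e, k_g = estimate_degradation_rates(
            datasets, model_kwargs.get("chx_duration", 15.0)
        )
        model_kwargs.setdefault("k_e", k_e)
        model_kwargs.setdefault("k_g", k_g)

    fits: dict[str, TopologyFitResults] = {}
    for i, topology in enumerate(topologies):
        model = TopologyFit(datasets, topology, **model_kwargs)
        fits[topology.to_string()] = model.fit(n_starts=n_starts, seed=int(seed) + i)
    best = min(r.error for r in fits.values())
    rows = [
        {
            "topology": key,
            "error": r.error,
            "error_ratio": r.error / best,
            "passes": r.error <= tolerance_factor * best,
        }
        for key, r in fits.items()
    ]
    leaderboard = pd.DataFrame(rows).sort_values("error", ignore_index=True)
    return leaderboard, fits
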