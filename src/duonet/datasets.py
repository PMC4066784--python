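"""Observed time-course containers and their tidy CSV dialect.

A :class:`TimeCourseDataset` holds the western-blot-style observations of
one experimental phase (depletion or recovery) under one perturbation:
per-time normalised mean levels and replicate standard deviations for the
two species.  On disk the data are tidy CSV with columns

    condition, phase, species, time_h, level, sd

plus a small sidecar (JSON/YAML) describing each condition's perturbation
schedule when one is needed beyond the default knockdown settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conditions import ExperimentalCondition

__all__ = ["TimeCourseDataset", "to_frame", "write_csv", "read_csv"]

PHASES = ("depletion", "recovery")
SPECIES = ("era", "gata3")


@dataclass(frozen=True)
class TimeCourseDataset:
    """Observations of one phase under one condition.

    ``times``, ``species``, ``levels`` and ``sds`` are parallel arrays, one
    entry per observation; ``species`` entries are ``"era"``/``"gata3"``.
    Recovery-phase times are measured from the cycloheximide washout.
    """

    condition: ExperimentalCondition
    phase: str
    times: np.ndarray
    species: np.ndarray
    levels: np.ndarray
    sds: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        times = np.asarray(self.times, dtype=float)
        species = np.asarray(self.species, dtype=object)
        levels = np.asarray(self.levels, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if not (times.shape == species.shape == levels.shape == sds.shape):
            raise ValueError("times, species, levels, sds must have equal shapes")
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if np.any(levels <= 0):
            raise ValueError("levels must be positive")
        if np.any(sds < 0):
            raise ValueError("standard deviations must be >= 0")
        for sp in species:
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")
        order = np.lexsort((times, np.asarray([SPECIES.index(s) for s in species])))
        object.__setattr__(self, "times", times[order])
        object.__setattr__(self, "species", species[order])
        object.__setattr__(self, "levels", levels[order])
        object.__setattr__(self, "sds", sds[order])

    def __len__(self) -> int:
        return self.times.size

    def series(self, species: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, levels, sds) of one species, time-sorted."""
        mask = self.species == species
        return self.times[mask], self.levels[mask], self.sds[mask]

    def unique_times(self) -> np.ndarray:
        return np.unique(self.times)

    @classmethod
    def from_arrays(
        cls,
        condition: ExperimentalCondition,
        phase: str,
        times: Sequence[float],
        era_levels: Sequence[float],
        gata3_levels: Sequence[float],
        era_sds: Sequence[float] | None = None,
        gata3_sds: Sequence[float] | None = None,
        n_replicates: int = 1,
    ) -> "TimeCourseDataset":
        """Build from per-species arrays on a shared time grid."""
        times = np.asarray(times, dtype=float)
        zeros = np.zeros_like(times)
        era_sds = zeros if era_sds is None else np.asarray(era_sds, dtype=float)
        gata3_sds = zeros if gata3_sds is None else np.asarray(gata3_sds, dtype=float)
        return cls(
            condition=condition,
            phase=phase,
            times=np.concatenate([times, times]),
            species=np.asarray(["era"] * times.size + ["gata3"] * times.size, dtype=object),
            levels=np.concatenate([np.asarray(era_levels, float), np.asarray(gata3_levels, float)]),
            sds=np.concatenate([era_sds, gata3_sds]),
            n_replicates=n_replicates,
        )


def to_frame(datasets: Iterable[TimeCourseDataset]) -> pd.DataFrame:
    """Concatenate datasets into one tidy DataFrame."""
    rows = []
    for ds in datasets:
        rows.append(
            pd.DataFrame(
                {
                    "condition": ds.condition.label,
                    "phase": ds.phase,
                    "species": ds.species.astype(str),
                    "time_h": ds.times,
                    "level": ds.levels,
                    "sd": ds.sds,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_csv(datasets: Iterable[TimeCourseDataset], path: str | Path) -> None:
    to_frame(datasets).to_csv(path, index=False)


def read_csv(
    path: str | Path,
    conditions: dict[str, ExperimentalCondition] | None = None,
) -> list[TimeCourseDataset]:
    """Read tidy CSV back into datasets.

    ``conditions`` maps condition labels to their perturbation schedules;
    labels ``control``, ``era_kd`` and ``gata3_kd`` fall back to the default
    knockdown settings when no mapping is supplied.
    """
    from .conditions import CONTROL, ERA_KNOCKDOWN, GATA3_KNOCKDOWN

    defaults = {"control": CONTROL, "era_kd": ERA_KNOCKDOWN, "gata3_kd": GATA3_KNOCKDOWN}
    df = pd.read_csv(path)
    required = {"condition", "phase", "species", "time_h", "level", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing columns: {sorted(missing)}")
    out = []
    for (label, phase), grp in df.groupby(["condition", "phase"], sort=True):
        cond = (conditions or {}).get(label, defaults.get(label))
        if cond is None:
            raise KeyError(f"no ExperimentalCondition provided for label {label!r}")
        out.append(
            TimeCourseDataset(
                condition=cond,
                phase=str(phase),
                times=grp["time_h"].to_numpy(float),
                species=grp["species"].to_numpy(object),
                levels=grp["level"].to_numpy(float),
                sds=grp["sd"].to_numpy(float),
            )
        )
    return out
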