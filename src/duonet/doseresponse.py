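"""Steady-state ICI dose–response of the ERα transcription proxy.

ICI 182,780 inactivates and depletes ERα protein without acting on its
transcription, so the response of the steady-state ERα mRNA proxy to an ICI
dose ladder discriminates the sign of ERα autoregulation: with positive
autoregulation the falling active-ERα level withdraws self-activation and
the proxy decreases monotonically, while without autoregulation the only
transcriptional effect is relief of the ERα→GATA3 repression (GATA3 rises
and further activates ERα transcription), so the proxy increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import CONTROL, ExperimentalCondition
from .model import mrna_proxy, steady_states
from .parameters import ModelParameters
from .topology import RegulatoryTopology

__all__ = ["DoseResponse", "ici_dose_response", "label_monotonicity", "MONOTONE_TOL"]

#: successive normalised differences beyond this magnitude count as moves
MONOTONE_TOL = 1e-4


@dataclass(frozen=True)
class DoseResponse:
    """Normalised steady-state proxy levels over an ICI dose ladder."""

    doses: np.ndarray
    levels: np.ndarray
    label: str
    #: per-dose list of stable-branch proxy values (length > 1 ⇒ multistable)
    branches: tuple[tuple[float, ...], ...] = field(default=())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"dose_nM": self.doses, "mrna_proxy": self.levels})


def label_monotonicity(levels: Sequence[float], tol: float = MONOTONE_TOL) -> str:
    """Classify a curve as increasing / decreasing / flat / non-monotone."""
    diffs = np.diff(np.asarray(levels, dtype=float))
    up = bool(np.any(diffs > tol))
    down = bool(np.any(diffs < -tol))
    if up and down:
        return "non-monotone"
    if up:
        return "increasing"
    if down:
        return "decreasing"
    return "flat"


def ici_dose_response(
    params: ModelParameters,
    doses: Sequence[float],
    topology: RegulatoryTopology | None = None,
    base_condition: ExperimentalCondition = CONTROL,
    tol: float = MONOTONE_TOL,
    box_hi: float = 10.0,
    ngrid: int = 25,
) -> DoseResponse:
    """Steady-state ERα mRNA proxy at each ICI dose, normalised to dose 0.

    ``doses`` must be sorted with the first entry 0.  At each dose all
    stable fixed points of the perturbed system are located; if more than
    one exists the curve is labelled ``"ambiguous"`` and every branch is
    reported, with the branch closest to the previous dose's level used for
    the main curve (continuation).
    """
    doses = np.asarray(doses, dtype=float)
    if doses[0] != 0.0:
        raise ValueError("dose ladder must start at 0")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if topology is not None:
        params.validate_topology(topology)

    levels = np.empty(doses.size)
    branches: list[tuple[float, ...]] = []
    ambiguous = False
    prev = None
    for i, dose in enumerate(doses):
        condition = base_condition.with_dose(dose)
        fps = steady_states(params, condition=condition, box_hi=box_hi, ngrid=ngrid)
        stable = [fp for fp, ok in fps if ok]
        if not stable:
            raise RuntimeError(f"no stable steady state at dose {dose} nM")
        values = tuple(mrna_proxy(params, fp, condition, normalize=True) for fp in stable)
        branches.append(values)
        if len(values) > 1:
            ambiguous = True
        if prev is None:
            value = values[0]
        else:  # continuation: follow the branch nearest the previous level
            value = min(values, key=lambda v: abs(v - prev))
        levels[i] = value
        prev = value

    levels = levels / levels[0]
    label = "ambiguous" if ambiguous else label_monotonicity(levels, tol)
    return DoseResponse(doses=doses, levels=levels, label=label, branches=tuple(branches))


#: default ICI ladder (nM) mirroring the experimental incubations
DEFAULT_DOSES = (0.0, 0.1, 1.0, 10.0, 100.0)
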