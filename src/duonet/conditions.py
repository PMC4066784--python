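"""Experimental perturbations applied to the network.

Three perturbations from the study design are representable:

* siRNA knockdown — scales the targeted gene's synthesis rate by
  ``1 - efficiency`` for the duration of the condition;
* cycloheximide (CHX) — a translation block that sets *both* synthesis
  rates to zero inside a time window;
* ICI 182,780 (fulvestrant) — sequesters ERα away from chromatin and
  induces its degradation independently of transcription.  Active ERα
  entering every regulatory Hill term is ``e / (1 + dose / ici_k50)`` and
  total ERα acquires an additional first-order loss
  ``ici_loss_rate * (dose / ici_k50) * e``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["ExperimentalCondition", "CONTROL", "ERA_KNOCKDOWN", "GATA3_KNOCKDOWN"]

_VALID_TARGETS = ("none", "era", "gata3")


@dataclass(frozen=True)
class ExperimentalCondition:
    """A perturbation schedule for one experiment.

    Parameters
    ----------
    sirna_target
        ``"none"``, ``"era"`` or ``"gata3"``; at most one target per
        condition.
    sirna_efficiency
        Fraction in [0, 1) by which the targeted synthesis rate is reduced.
    chx_window
        Optional ``(t_on, t_off)`` in hours during which both synthesis
        rates are zero (cycloheximide).
    ici_dose
        ICI concentration in nM (>= 0).
    ici_k50
        Dose at which ERα inactivation is half-maximal, nM.
    ici_loss_rate
        First-order ERα loss rate per unit ``dose / ici_k50``, per hour.
    label
        Optional short name used in tidy tables (defaults to a derived one).
    """

    sirna_target: str = "none"
    sirna_efficiency: float = 0.9
    chx_window: Optional[tuple[float, float]] = None
    ici_dose: float = 0.0
    ici_k50: float = 1.0
    ici_loss_rate: float = 0.1
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sirna_target not in _VALID_TARGETS:
            raise ValueError(
                f"unknown siRNA target {self.sirna_target!r}; expected one of {_VALID_TARGETS}"
            )
        if not 0.0 <= self.sirna_efficiency < 1.0:
            raise ValueError("sirna_efficiency must lie in [0, 1)")
        if self.chx_window is not None:
            t_on, t_off = self.chx_window
            if not t_on < t_off:
                raise ValueError("chx_window must satisfy t_on < t_off")
            object.__setattr__(self, "chx_window", (float(t_on), float(t_off)))
        if self.ici_dose < 0:
            raise ValueError("ici_dose must be >= 0")
        if self.ici_k50 <= 0 or self.ici_loss_rate < 0:
            raise ValueError("ici_k50 must be > 0 and ici_loss_rate >= 0")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.sirna_target == "none":
            base = "control"
        else:
            base = f"{self.sirna_target}_kd"
        if self.ici_dose > 0:
            base += f"_ici{self.ici_dose:g}"
        return base

    # -- derived quantities ---------------------------------------------
    @property
    def synthesis_scales(self) -> tuple[float, float]:
        """Multiplicative scales (s_e, s_g) on the two synthesis rates."""
        s_e = 1.0 - self.sirna_efficiency if self.sirna_target == "era" else 1.0
        s_g = 1.0 - self.sirna_efficiency if self.sirna_target == "gata3" else 1.0
        return (s_e, s_g)

    @property
    def ici_activity_factor(self) -> float:
        """Fraction of ERα remaining active in the Hill terms."""
        return 1.0 / (1.0 + self.ici_dose / self.ici_k50)

    @property
    def ici_degradation_rate(self) -> float:
        """Additional first-order loss rate of total ERα, per hour."""
        return self.ici_loss_rate * (self.ici_dose / self.ici_k50)

    def packed(self, chx_active: bool = False) -> np.ndarray:
        """Flat vector ``[s_e, s_g, ici_alpha, d_ici]`` for the kernels.

        ``chx_active`` zeroes both synthesis scales (the integrator splits
        the timeline at the window boundaries and passes the flag per
        segment).
        """
        s_e, s_g = (0.0, 0.0) if chx_active else self.synthesis_scales
        return np.array([s_e, s_g, self.ici_activity_factor, self.ici_degradation_rate])

    def with_dose(self, dose: float) -> "ExperimentalCondition":
        """Copy with a different ICI dose (label re-derived)."""
        return replace(self, ici_dose=float(dose), label=None)

    def with_chx(self, t_on: float, t_off: float) -> "ExperimentalCondition":
        """Copy with a cycloheximide window added."""
        return replace(self, chx_window=(t_on, t_off))


#: Unperturbed (control siRNA) condition.
CONTROL = ExperimentalCondition(sirna_target="none")
#: ERα knockdown at the default 90% efficiency.
ERA_KNOCKDOWN = ExperimentalCondition(sirna_target="era")
#: GATA3 knockdown at the default 90% efficiency.
GATA3_KNOCKDOWN = ExperimentalCondition(sirna_target="gata3")
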