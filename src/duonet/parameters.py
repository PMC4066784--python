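"""Dimensionless model parameters and the fitting parameter space.

Concentrations are normalised by the unperturbed cellular levels, so the
wild-type steady state is (e, g) = (1, 1) and all parameters except the
degradation rates (per hour) are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .topology import RegulatoryTopology, Sign

__all__ = [
    "ModelParameters",
    "ParameterBounds",
    "PACKED_SIZE",
]

#: length of the packed parameter vector used by the numerical kernels
PACKED_SIZE = 16


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the two-gene Hill-regulation ODE model.

    Attributes
    ----------
    b_e, b_g
        Dimensionless basal synthesis rates (normalised by the wild-type
        protein levels).  Usually determined by :meth:`normalized` so that
        (1, 1) is the unperturbed steady state.
    k_e, k_g
        First-order degradation (plus dilution) rates, per hour.
    f, K, n
        Length-4 arrays of Hill fold changes, half-saturation levels
        (normalised units) and effective cooperativities for links
        j = 1..4.  ``f[j-1] > 1`` is activation, ``< 1`` repression and
        ``== 1`` no regulation.
    """

    b_e: float
    b_g: float
    k_e: float
    k_g: float
    f: np.ndarray = field(default_factory=lambda: np.ones(4))
    K: np.ndarray = field(default_factory=lambda: np.ones(4))
    n: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self) -> None:
        for name in ("f", "K", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (4,):
                raise ValueError(f"{name} must have shape (4,), got {arr.shape}")
            object.__setattr__(self, name, arr)
        packed = self.packed()
        if not np.all(np.isfinite(packed)):
            raise ValueError("parameters must be finite")
        if np.any(packed <= 0.0):
            raise ValueError("all parameters must be strictly positive")
        if np.any(self.n < 1.0):
            raise ValueError("cooperativities n_j must be >= 1")

    # -- packing ---------------------------------------------------------
    def packed(self) -> np.ndarray:
        """Flat vector ``[b_e, b_g, k_e, k_g, f1..f4, K1..K4, n1..n4]``."""
        return np.concatenate(([self.b_e, self.b_g, self.k_e, self.k_g], self.f, self.K, self.n))

    @classmethod
    def from_packed(cls, p: np.ndarray) -> "ModelParameters":
        p = np.asarray(p, dtype=float)
        if p.shape != (PACKED_SIZE,):
            raise ValueError(f"packed vector must have length {PACKED_SIZE}")
        return cls(p[0], p[1], p[2], p[3], p[4:8].copy(), p[8:12].copy(), p[12:16].copy())

    # -- construction helpers -------------------------------------------
    def replace(self, **kwargs) -> "ModelParameters":
        """Copy with the given fields replaced."""
        return replace(self, **kwargs)

    def with_fold(self, j: int, f: float, K: float | None = None, n: float | None = None) -> "ModelParameters":
        """Copy with the Hill parameters of link ``j`` (1-based) replaced."""
        fs, Ks, ns = self.f.copy(), self.K.copy(), self.n.copy()
        fs[j - 1] = f
        if K is not None:
            Ks[j - 1] = K
        if n is not None:
            ns[j - 1] = n
        return self.replace(f=fs, K=Ks, n=ns)

    # -- validation ------------------------------------------------------
    def validate_topology(self, topology: RegulatoryTopology) -> None:
        """Raise if the fold changes violate the topology's sign constraints."""
        for j in range(1, 5):
            sign = topology.sign(j)
            if not sign.admits_fold(float(self.f[j - 1])):
                raise ValueError(
                    f"fold f_{j}={self.f[j - 1]:g} inconsistent with sign "
                    f"'{sign.value}' of link {j}"
                )

    def topology(self, atol: float = 0.0) -> RegulatoryTopology:
        """Infer the sign topology implied by the fold changes."""
        signs = []
        for fj in self.f:
            if abs(fj - 1.0) <= atol:
                signs.append(Sign.NULL)
            elif fj > 1.0:
                signs.append(Sign.POSITIVE)
            else:
                signs.append(Sign.NEGATIVE)
        return RegulatoryTopology(*signs)

    # -- normalisation ---------------------------------------------------
    def normalized(self) -> "ModelParameters":
        """Rescale basal rates so (1, 1) is the unperturbed steady state.

        Sets ``b_e = k_e / (F1(1) * F2(1))`` and ``b_g = k_g / (F3(1) * F4(1))``
        so that both time derivatives vanish exactly at the normalised
        wild-type point.  Idempotent; all other parameters unchanged.
        """
        from ._kernels import hill_fold_scalar

        F = [hill_fold_scalar(1.0, self.f[j], self.K[j], self.n[j]) for j in range(4)]
        return self.replace(b_e=self.k_e / (F[0] * F[1]), b_g=self.k_g / (F[2] * F[3]))

    def summary_dict(self) -> Mapping[str, float]:
        d = {"b_e": self.b_e, "b_g": self.b_g, "k_e": self.k_e, "k_g": self.k_g}
        for j in range(4):
            d[f"f_{j + 1}"] = float(self.f[j])
            d[f"K_{j + 1}"] = float(self.K[j])
            d[f"n_{j + 1}"] = float(self.n[j])
        return d


def normalize_to_wt(params: ModelParameters, topology: RegulatoryTopology | None = None) -> ModelParameters:
    """Functional form of :meth:`ModelParameters.normalized`.

    If a topology is given the parameters are validated against it first.
    """
    if topology is not None:
        params.validate_topology(topology)
    return params.normalized()


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints used by the multi-start optimiser.

    Defaults keep the search in a biophysically plausible and numerically
    stable region: fold changes in (1, 50] for activation and [0.02, 1) for
    repression (the open ends at 1 are realised at one part in 10^6, so a
    null-like optimum can be approached arbitrarily closely), half
    saturations in [0.05, 20] normalised units, cooperativities in [1, 4]
    and degradation rates corresponding to half-lives of 0.5–24 h.
    """

    f_pos: tuple[float, float] = (1.0 + 1e-6, 50.0)
    f_neg: tuple[float, float] = (0.02, 1.0 - 1e-6)
    K: tuple[float, float] = (0.05, 20.0)
    n: tuple[float, float] = (1.0, 4.0)
    half_life_h: tuple[float, float] = (0.5, 24.0)

    def fold_bounds(self, sign: Sign) -> tuple[float, float]:
        if sign is Sign.POSITIVE:
            return self.f_pos
        if sign is Sign.NEGATIVE:
            return self.f_neg
        return (1.0, 1.0)

    def degradation_bounds(self) -> tuple[float, float]:
        lo, hi = self.half_life_h
        return (np.log(2.0) / hi, np.log(2.0) / lo)
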