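"""Sign topologies of the two-gene regulatory network.

The network has four regulatory links, indexed ``j = 1..4``:

1. ERα autoregulation            (ERα → ERα)
2. activation of ERα by GATA3    (GATA3 → ERα)
3. regulation of GATA3 by ERα    (ERα → GATA3)
4. GATA3 autoregulation          (GATA3 → GATA3)

Each link carries one of three signs — positive, negative or null — so the
network admits 3**4 = 81 sign topologies.  A sign constrains the fold change
``f_j`` of the corresponding Hill regulation function: positive means
``f_j > 1``, negative ``0 < f_j < 1`` and null ``f_j = 1`` (no regulation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Sign(str, Enum):
    """Sign of a regulatory link."""

    POSITIVE = "+"
    NEGATIVE = "-"
    NULL = "0"

    def admits_fold(self, f: float) -> bool:
        """Whether a fold change ``f`` is consistent with this sign."""
        if self is Sign.POSITIVE:
            return f > 1.0
        if self is Sign.NEGATIVE:
            return 0.0 < f < 1.0
        return f == 1.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Names of the four links in index order j = 1..4.
LINK_NAMES: tuple[str, ...] = (
    "era_auto",
    "gata3_to_era",
    "era_to_gata3",
    "gata3_auto",
)

# enumeration order: lexicographic by link index, then by this sign order
_SIGN_ORDER: tuple[Sign, ...] = (Sign.POSITIVE, Sign.NEGATIVE, Sign.NULL)


@dataclass(frozen=True)
class RegulatoryTopology:
    """An assignment of signs to the four regulatory links.

    Parameters
    ----------
    era_auto, gata3_to_era, era_to_gata3, gata3_auto
        Signs of links j = 1..4.  Accepts :class:`Sign` members or their
        string values ``"+"``, ``"-"``, ``"0"``.
    """

    era_auto: Sign
    gata3_to_era: Sign
    era_to_gata3: Sign
    gata3_auto: Sign

    def __post_init__(self) -> None:
        for name in LINK_NAMES:
            value = getattr(self, name)
            if not isinstance(value, Sign):
                object.__setattr__(self, name, Sign(value))

    @property
    def signs(self) -> tuple[Sign, Sign, Sign, Sign]:
        """Signs as a tuple ordered by link index j = 1..4."""
        return tuple(getattr(self, name) for name in LINK_NAMES)  # type: ignore[return-value]

    def sign(self, j: int) -> Sign:
        """Sign of link ``j`` (1-based, as in the link indexing above)."""
        if not 1 <= j <= 4:
            raise ValueError(f"link index must be in 1..4, got {j}")
        return self.signs[j - 1]

    def with_sign(self, j: int, sign: Sign | str) -> "RegulatoryTopology":
        """Return a copy with link ``j`` set to ``sign``."""
        signs = list(self.signs)
        signs[j - 1] = Sign(sign)
        return RegulatoryTopology(*signs)

    @classmethod
    def from_string(cls, s: str) -> "RegulatoryTopology":
        """Parse a compact 4-character string such as ``"0+-+"``."""
        if len(s) != 4:
            raise ValueError(f"expected 4 sign characters, got {s!r}")
        return cls(*(Sign(c) for c in s))

    def to_string(self) -> str:
        """Compact 4-character representation, e.g. ``"0+-+"``."""
        return "".join(sign.value for sign in self.signs)

    def __str__(self) -> str:
        return self.to_string()

    def free_links(self) -> tuple[int, ...]:
        """Indices of non-null links (these carry free Hill parameters)."""
        return tuple(j for j in range(1, 5) if self.sign(j) is not Sign.NULL)

    def describe(self) -> str:
        """Human-readable one-line description."""
        parts = [f"{name}:{sign.value}" for name, sign in zip(LINK_NAMES, self.signs)]
        return " ".join(parts)


#: The network concluded by the analysis: no ERα autoregulation, GATA3
#: activates ERα, ERα represses GATA3 (an overall negative feedback) and
#: GATA3 positively autoregulates.
CONSENSUS_TOPOLOGY = RegulatoryTopology(Sign.NULL, Sign.POSITIVE, Sign.NEGATIVE, Sign.POSITIVE)

#: Cross-regulation signs as determined from the knockdown steady-state
#: shifts (GATA3 → ERα positive, ERα → GATA3 negative).
CROSS_LINK_SIGNS: Mapping[int, Sign] = {2: Sign.POSITIVE, 3: Sign.NEGATIVE}


def enumerate_topologies(
    free_links: Iterable[int] | None = None,
    fixed_signs: Mapping[int, Sign | str] | None = None,
) -> list[RegulatoryTopology]:
    """Enumerate all sign assignments over a subset of free links.

    Parameters
    ----------
    free_links
        Link indices (1-based) that range over all three signs.  Defaults to
        all four links, yielding the full 3**4 = 81 topologies.
    fixed_signs
        Mapping from the remaining link indices to their fixed sign.  Links
        absent from both specifications default to null.

    Returns
    -------
    list of RegulatoryTopology
        Deterministically ordered: lexicographic by link index with sign
        order ``+, -, 0``.

    Examples
    --------
    >>> len(enumerate_topologies())
    81
    >>> len(enumerate_topologies(free_links=[1, 4], fixed_signs={2: "+", 3: "-"}))
    9
    """
    free = tuple(sorted(set(int(j) for j in (free_links if free_links is not None else (1, 2, 3, 4)))))
    fixed = {int(j): Sign(s) for j, s in (fixed_signs or {}).items()}
    if any(j < 1 or j > 4 for j in itertools.chain(free, fixed)):
        raise ValueError("link indices must be in 1..4")
    overlap = set(free) & set(fixed)
    if overlap:
        raise ValueError(f"links specified both free and fixed: {sorted(overlap)}")

    base = [fixed.get(j, Sign.NULL) for j in range(1, 5)]
    out: list[RegulatoryTopology] = []
    for combo in itertools.product(_SIGN_ORDER, repeat=len(free)):
        signs = list(base)
        for j, sign in zip(free, combo):
            signs[j - 1] = sign
        out.append(RegulatoryTopology(*signs))
    return out


def autoregulation_topologies(
    cross_signs: Mapping[int, Sign | str] | None = None,
) -> list[RegulatoryTopology]:
    """The nine topologies with free autoregulation and fixed cross-links.

    With the cross-regulation signs pinned by the knockdown experiments
    (GATA3 → ERα positive, ERα → GATA3 negative), the two autoregulatory
    links each range over 3 signs, giving 3**2 = 9 candidate topologies.
    """
    fixed = dict(cross_signs) if cross_signs is not None else dict(CROSS_LINK_SIGNS)
    return enumerate_topologies(free_links=[1, 4], fixed_signs=fixed)


def sorted_topology_labels(topologies: Sequence[RegulatoryTopology]) -> list[str]:
    """Compact string labels for a sequence of topologies."""
    return [t.to_string() for t in topologies]
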