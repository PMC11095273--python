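"""Coronary circulation patterns.

The CatLet angiographic scoring system classifies every coronary tree into
one of 54 circulation patterns, defined by the cross of three anatomic axes:

* LAD length — how far the left anterior descending artery wraps around the
  apex (short / average / long);
* diagonal size — the calibre of the diagonal branches (small / intermediate
  / large);
* dominance — which artery supplies the posterior descending territory
  (six right-coronary-artery variants, including PDA-only and PDA-zero).

The pattern determines how myocardial-supply weight is distributed over the
coronary segments, so it is the key into the segment-weight table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator


class LadLength(str, Enum):
    SHORT = "short"
    AVERAGE = "average"
    LONG = "long"


class DiagonalSize(str, Enum):
    SMALL = "small"
    INTERMEDIATE = "intermediate"
    LARGE = "large"


class Dominance(str, Enum):
    AVERAGE_RCA = "average_rca"
    LARGE_RCA = "large_rca"
    SMALL_RCA = "small_rca"
    SUPER_RCA = "super_rca"
    PDA_ONLY = "pda_only"
    PDA_ZERO = "pda_zero"


#: synonyms accepted on input (case-insensitive, spaces/hyphens fold to "_")
_ALIASES = {
    "inter": DiagonalSize.INTERMEDIATE,
    "intermediate": DiagonalSize.INTERMEDIATE,
    "avg": LadLength.AVERAGE,
}


@dataclass(frozen=True, order=True)
class CoronaryPatternKey:
    """One of the 54 coronary circulation patterns."""

    lad_length: LadLength
    diagonal_size: DiagonalSize
    dominance: Dominance

    def __str__(self) -> str:
        return f"{self.lad_length.value}|{self.diagonal_size.value}|{self.dominance.value}"

    @classmethod
    def from_string(cls, text: str) -> "CoronaryPatternKey":
        parts = text.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"pattern key {text!r} must have form '<lad>|<diagonal>|<dominance>'"
            )
        return resolve_pattern(*parts)


def _canonicalize(label: str, enum_cls: type[Enum]) -> Enum:
    token = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    alias = _ALIASES.get(token)
    if isinstance(alias, enum_cls):
        return alias
    try:
        return enum_cls(token)
    except ValueError:
        legal = ", ".join(member.value for member in enum_cls)
        raise ValueError(
            f"unknown {enum_cls.__name__} label {label!r}; legal labels: {legal}"
        ) from None


def resolve_pattern(
    lad_length: str | LadLength,
    diagonal_size: str | DiagonalSize,
    dominance: str | Dominance,
) -> CoronaryPatternKey:
    """Canonicalize the three anatomic labels into a pattern key.

    Labels are accepted case-insensitively with spaces or hyphens
    (``"PDA only"`` → ``pda_only``). Unknown labels raise ``ValueError``
    listing the legal labels for that axis.
    """
    return CoronaryPatternKey(
        lad_length=_canonicalize(lad_length, LadLength),
        diagonal_size=_canonicalize(diagonal_size, DiagonalSize),
        dominance=_canonicalize(dominance, Dominance),
    )


def all_patterns() -> Iterator[CoronaryPatternKey]:
    """Enumerate all 54 pattern keys in a stable, documented order.

    Order is LAD length (short, average, long) × diagonal size (small,
    intermediate, large) × dominance (enum declaration order). Config files
    may rely on this order for indexing.
    """
    for lad, dx, dom in itertools.product(LadLength, DiagonalSize, Dominance):
        yield CoronaryPatternKey(lad, dx, dom)


N_PATTERNS = 54
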