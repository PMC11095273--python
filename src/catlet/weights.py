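"""Segment-weight tables for the CatLet score.

A weight table assigns, for each of the 54 coronary circulation patterns, a
positive myocardial-supply weight to every scoreable coronary segment. The
published calculator's weights are proprietary, so weights are treated as
external configuration here: tables are loaded from JSON or long-format CSV
and validated (all 54 patterns present, all weights positive, per-pattern
sums equal to the declared normalization constant).

The module also ships :func:`illustrative_weight_table`, a clearly-labelled
synthetic default built from a simplified coronary tree: 17 units of
myocardial territory (the 17-segment model) are partitioned over terminal
branches according to the pattern's anatomy, each segment's weight is the
territory downstream of it (flow conservation: a parent segment carries the
supply of everything distal to it), and each pattern is rescaled to a common
normalization constant. It is NOT the published CatLet weighting; every
downstream statistic is parameterized by whichever table is active.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .patterns import CoronaryPatternKey, Dominance, LadLength, DiagonalSize, all_patterns

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SegmentWeightTable:
    """Per-pattern map from segment identifier to supply weight."""

    name: str
    normalization: float
    patterns: Mapping[CoronaryPatternKey, Mapping[str, float]] = field(repr=False)

    def __post_init__(self) -> None:
        keys = set(self.patterns)
        expected = set(all_patterns())
        missing = expected - keys
        if missing:
            raise ValidationError(
                f"weight table {self.name!r} missing {len(missing)} pattern(s), "
                f"e.g. {sorted(map(str, missing))[:3]}"
            )
        extra = keys - expected
        if extra:
            raise ValidationError(
                f"weight table {self.name!r} has unknown pattern(s): "
                f"{sorted(map(str, extra))[:3]}"
            )
        for key, segs in self.patterns.items():
            if not segs:
                raise ValidationError(f"pattern {key} has no segments")
            for seg, w in segs.items():
                if not (w > 0) or not math.isfinite(w):
                    raise ValidationError(
                        f"pattern {key} segment {seg!r}: weight must be > 0, got {w}"
                    )
            total = math.fsum(segs.values())
            if abs(total - self.normalization) > _SUM_TOL * max(1.0, self.normalization):
                raise ValidationError(
                    f"pattern {key}: weights sum to {total!r}, expected "
                    f"normalization constant {self.normalization!r}"
                )

    def weight(self, pattern: CoronaryPatternKey, segment_id: str) -> float:
        segs = self.patterns.get(pattern)
        if segs is None:
            raise ConfigurationError(f"pattern {pattern} absent from table {self.name!r}")
        try:
            return segs[segment_id]
        except KeyError:
            raise ConfigurationError(
                f"segment {segment_id!r} is not defined for pattern {pattern} "
                f"in weight table {self.name!r}"
            ) from None

    def segments(self, pattern: CoronaryPatternKey) -> dict[str, float]:
        return dict(self.patterns[pattern])

    # ------------------------------------------------------------------ IO

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "normalization": self.normalization,
            "patterns": {str(k): dict(v) for k, v in self.patterns.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentWeightTable":
        payload = json.loads(Path(path).read_text())
        patterns = {
            CoronaryPatternKey.from_string(k): {s: float(w) for s, w in v.items()}
            for k, v in payload["patterns"].items()
        }
        return cls(
            name=payload.get("name", Path(path).stem),
            normalization=float(payload["normalization"]),
            patterns=patterns,
        )

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "SegmentWeightTable":
        """Long format: columns pattern, segment, weight (one row per weight)."""
        df = pd.read_csv(path)
        required = {"pattern", "segment", "weight"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"weight CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        patterns: dict[CoronaryPatternKey, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            key = CoronaryPatternKey.from_string(str(row.pattern))
            patterns.setdefault(key, {})[str(row.segment)] = float(row.weight)
        norms = {round(math.fsum(v.values()), 9) for v in patterns.values()}
        normalization = norms.pop() if len(norms) == 1 else float("nan")
        return cls(name=name or Path(path).stem, normalization=normalization, patterns=patterns)


# ---------------------------------------------------------------- default

#: territory (in 17ths of the left ventricle) perfused via the posterior
#: circulation, by dominance: (PDA, posterolateral branch, LCX posterior share)
_POSTERIOR_SPLIT = {
    Dominance.AVERAGE_RCA: (2.0, 1.0, 0.75),
    Dominance.LARGE_RCA: (2.5, 1.5, 0.25),
    Dominance.SMALL_RCA: (1.25, 0.75, 1.75),
    Dominance.SUPER_RCA: (3.0, 2.0, 0.0),
    Dominance.PDA_ONLY: (2.25, 0.0, 1.5),
    Dominance.PDA_ZERO: (0.0, 0.0, 3.75),
}

_DIAGONAL_TERRITORY = {
    DiagonalSize.SMALL: (1.0, 0.0),
    DiagonalSize.INTERMEDIATE: (1.2, 0.8),
    DiagonalSize.LARGE: (1.8, 1.2),
}

_APEX_TERRITORY = {LadLength.SHORT: 0.75, LadLength.AVERAGE: 1.5, LadLength.LONG: 2.25}

DEFAULT_NORMALIZATION = 40.0


def _pattern_weights(key: CoronaryPatternKey) -> dict[str, float]:
    """Territory partition + flow-conservation roll-up for one pattern."""
    d1, d2 = _DIAGONAL_TERRITORY[key.diagonal_size]
    apex = _APEX_TERRITORY[key.lad_length]
    pda, plb, cx_post = _POSTERIOR_SPLIT[key.dominance]

    sept_prox, sept_mid = 1.5, 1.0       # septal territory off LAD prox/mid
    rv_prox, rv_mid = 0.5, 0.5           # right-ventricular marginals
    cx_own, cx_dist = 0.5, 1.0 + cx_post

    has_rca_mid = pda > 0 and key.dominance is not Dominance.PDA_ONLY
    rca_terminal = rv_prox + (rv_mid if has_rca_mid else 0.0) + pda + plb

    lateral = 17.0 - (
        sept_prox + sept_mid + apex + d1 + d2 + rca_terminal + cx_own + cx_dist
    )
    om1, om2 = 0.6 * lateral, 0.4 * lateral

    # cumulative (downstream-territory) weights
    w: dict[str, float] = {}
    w["LAD-dist"] = apex
    w["D1"] = d1
    if d2 > 0:
        w["D2"] = d2
    w["LAD-mid"] = sept_mid + w["LAD-dist"] + d2
    w["LAD-prox"] = sept_prox + w["LAD-mid"] + d1
    w["OM1"] = om1
    w["OM2"] = om2
    w["LCX-dist"] = cx_dist
    w["LCX-prox"] = cx_own + om1 + om2 + cx_dist
    w["LM"] = w["LAD-prox"] + w["LCX-prox"]
    if pda > 0:
        w["PDA"] = pda
    if plb > 0:
        w["PLB"] = plb
    if has_rca_mid:
        w["RCA-mid"] = rv_mid + pda + plb
        w["RCA-prox"] = rv_prox + w["RCA-mid"]
    else:
        w["RCA-prox"] = rv_prox + pda  # PDA-only: prox feeds the PDA directly
    scale = DEFAULT_NORMALIZATION / math.fsum(w.values())
    return {seg: wt * scale for seg, wt in w.items()}


def illustrative_weight_table() -> SegmentWeightTable:
    """Synthetic default weight table (documented in docs/methods.md).

    Illustrative only — not the published CatLet weights, which are external
    configuration. Suitable for simulation and for exercising the pipeline.
    """
    return SegmentWeightTable(
        name="illustrative-synthetic",
        normalization=DEFAULT_NORMALIZATION,
        patterns={key: _pattern_weights(key) for key in all_patterns()},
    )
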