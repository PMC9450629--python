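"""Quantized-chord ("digitized ruler") walk along a canal centerline.

The measurement protocol places straight chords of predefined lengths end to
end along the curve, vestibule to apex: a mandatory prefix of six 2.0 mm
chords (R1-R6), then greedily the largest of {2.0, 1.5, 1.0} mm whose chord
both reaches the curve and stays within a perpendicular deviation tolerance
of the sub-curve it spans.  Summing the nominal chord lengths gives the total
canal length; because a chord never exceeds the arc it spans, the total
systematically underestimates the true arc length on curved canals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import PrefixInfeasibleError, RunawayWalkError
from .phantom import CenterlineCurve

__all__ = [
    "RulerScheme",
    "Segment",
    "SegmentTable",
    "ChordPlacement",
    "BiasReport",
    "place_chord",
    "chord_walk",
    "sum_segments",
    "chord_bias",
]

# Numerical tolerances for chord placement on the interpolated polyline.
_ROOT_TOL = 1e-9          # bisection/brentq tolerance on end_arc, mm
_CROSS_TOL = 1e-9         # slack when testing whether a chord just reaches


@dataclass(frozen=True)
class RulerScheme:
    """The measurement protocol: chord lengths, tolerance, termination guard."""

    fixed_prefix: tuple[float, ...] = (2.0,) * 6
    allowed_set: tuple[float, ...] = (2.0, 1.5, 1.0)
    deviation_tol: float = 0.5
    max_segments: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_prefix", tuple(self.fixed_prefix))
        object.__setattr__(self, "allowed_set", tuple(self.allowed_set))
        if any(length <= 0 for length in self.fixed_prefix + self.allowed_set):
            raise ValueError("all ruler lengths must be > 0")
        if not self.allowed_set:
            raise ValueError("allowed_set must be non-empty")
        if list(self.allowed_set) != sorted(self.allowed_set, reverse=True) or len(
            set(self.allowed_set)
        ) != len(self.allowed_set):
            raise ValueError("allowed_set must be sorted strictly descending")
        if self.deviation_tol < 0:
            raise ValueError("deviation_tol must be >= 0")
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RulerScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            fixed_prefix=tuple(d.get("fixed_prefix", (2.0,) * 6)),
            allowed_set=tuple(d.get("allowed_set", (2.0, 1.5, 1.0))),
            deviation_tol=float(d.get("deviation_tol_mm", 0.5)),
            max_segments=int(d.get("max_segments", 100)),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fixed_prefix": list(self.fixed_prefix),
            "allowed_set": list(self.allowed_set),
            "deviation_tol_mm": self.deviation_tol,
            "max_segments": self.max_segments,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class Segment:
    """One placed chord: label, nominal length, endpoints and arc positions."""

    label: str
    nominal_length: float
    start_point: tuple[float, float, float]
    end_point: tuple[float, float, float]
    start_arc: float
    end_arc: float


@dataclass
class SegmentTable:
    """Ordered chord placements plus termination bookkeeping."""

    segments: list[Segment] = field(default_factory=list)
    terminated_with_remainder: bool = False
    remainder_arc: float = 0.0

    @property
    def total(self) -> float:
        """Sum of nominal chord lengths (exact for 0.5 mm multiples)."""
        return float(sum(seg.nominal_length for seg in self.segments))

    def __len__(self) -> int:
        return len(self.segments)

    def lengths(self) -> list[float]:
        return [seg.nominal_length for seg in self.segments]


class ChordPlacement(NamedTuple):
    end_arc: float
    max_deviation: float


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance from each point to the line segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def place_chord(
    curve: CenterlineCurve, start_arc: float, length: float
) -> Optional[ChordPlacement]:
    """Lay a chord of ``length`` forward from ``start_arc`` along the curve.

    Returns the smallest ``end_arc > start_arc`` at which the straight-line
    distance from ``curve(start_arc)`` first equals ``length`` (bracketing on
    the polyline vertices, then root refinement; within one linear segment the
    distance to a fixed point is convex, so the bracketed first crossing is
    unique).  Also returns the maximum perpendicular deviation of the spanned
    sub-curve from the chord.  Returns ``None`` if the chord never reaches
    ``length`` before the curve's end.
    """
    total = curve.total_length
    if not (0.0 <= start_arc < total):
        raise ValueError(f"start_arc must be in [0, {total}); got {start_arc}")
    if length <= 0:
        raise ValueError("length must be > 0")

    s = curve.cumulative_arc
    pts = curve.points
    p0 = curve.point_at(start_arc)

    i0 = int(np.searchsorted(s, start_arc, side="right"))
    if i0 >= len(s):
        return None
    d = np.linalg.norm(pts[i0:] - p0, axis=1) - length
    crossing = np.nonzero(d >= -_CROSS_TOL)[0]
    if crossing.size == 0:
        return None
    j = i0 + int(crossing[0])
    lo = start_arc if j == i0 else float(s[j - 1])
    hi = float(s[j])

    def f(arc: float) -> float:
        return float(np.linalg.norm(curve.point_at(arc) - p0)) - length

    if f(hi) <= 0.0:
        end_arc = hi  # chord just reaches the bracket end (within tolerance)
    else:
        end_arc = float(brentq(f, lo, hi, xtol=_ROOT_TOL))
    if end_arc <= start_arc:
        return None

    p1 = curve.point_at(end_arc)
    interior = pts[(s > start_arc) & (s < end_arc)]
    if interior.size:
        max_dev = float(_point_segment_distance(interior, p0, p1).max())
    else:
        max_dev = 0.0
    return ChordPlacement(end_arc=end_arc, max_deviation=max_dev)


def chord_walk(curve: CenterlineCurve, scheme: RulerScheme | None = None) -> SegmentTable:
    """Walk the curve with the ruler scheme, vestibule to apex.

    Places the fixed prefix (R1..R6 by default) unconditionally, then
    repeatedly the largest allowed length whose chord (a) crosses before the
    curve end and (b) deviates from the spanned sub-curve by at most
    ``deviation_tol``.  Stops when no allowed ruler fits, recording the
    unmeasured remainder arc.

    Raises
    ------
    PrefixInfeasibleError
        If a mandatory prefix chord finds no crossing (curve too short).
    RunawayWalkError
        If more than ``max_segments`` chords are placed.
    """
    if scheme is None:
        scheme = RulerScheme()
    total = curve.total_length
    table = SegmentTable()
    start = 0.0

    def _append(length: float, placement: ChordPlacement) -> None:
        nonlocal start
        label = f"R{len(table.segments) + 1}"
        p0 = curve.point_at(start)
        p1 = curve.point_at(placement.end_arc)
        table.segments.append(
            Segment(
                label=label,
                nominal_length=length,
                start_point=tuple(float(v) for v in p0),
                end_point=tuple(float(v) for v in p1),
                start_arc=start,
                end_arc=placement.end_arc,
            )
        )
        start = placement.end_arc

    for length in scheme.fixed_prefix:
        if len(table.segments) >= scheme.max_segments:
            raise RunawayWalkError(
                f"walk exceeded max_segments={scheme.max_segments}"
            )
        placement = place_chord(curve, start, length) if start < total else None
        if placement is None:
            raise PrefixInfeasibleError(
                f"mandatory {length} mm chord "
                f"{f'R{len(table.segments) + 1}'} finds no crossing "
                f"(curve arc {total:.3f} mm)"
            )
        _append(length, placement)

    while start < total - _CROSS_TOL:
        if len(table.segments) >= scheme.max_segments:
            raise RunawayWalkError(
                f"walk exceeded max_segments={scheme.max_segments}"
            )
        placed = False
        for length in scheme.allowed_set:
            placement = place_chord(curve, start, length)
            if placement is not None and placement.max_deviation <= scheme.deviation_tol:
                _append(length, placement)
                placed = True
                break
        if not placed:
            break

    remainder = max(0.0, total - start)
    table.remainder_arc = remainder
    table.terminated_with_remainder = remainder > _CROSS_TOL
    if not table.terminated_with_remainder:
        table.remainder_arc = 0.0
    return table


def sum_segments(table: SegmentTable | Sequence[float]) -> float:
    """Total canal length: exact sum of nominal chord lengths in mm."""
    if isinstance(table, SegmentTable):
        return table.total
    return float(sum(table))


class BiasReport(NamedTuple):
    chord_total: float
    spanned_arc: float
    remainder_arc: float
    relative_underestimate: float


def chord_bias(curve: CenterlineCurve, scheme: RulerScheme | None = None) -> BiasReport:
    """Quantify the chord-vs-arc underestimation of the walk on ``curve``.

    ``relative_underestimate = 1 - chord_total / (spanned_arc + remainder)``,
    the fraction of true polyline arc missed by the quantized-chord total.
    ``chord_total <= spanned_arc`` always (a chord never exceeds its arc).
    """
    table = chord_walk(curve, scheme)
    spanned = table.segments[-1].end_arc if table.segments else 0.0
    remainder = table.remainder_arc
    chord_total = table.total
    denom = spanned + remainder
    rel = 1.0 - chord_total / denom if denom > 0 else 0.0
    return BiasReport(
        chord_total=chord_total,
        spanned_arc=spanned,
        remainder_arc=remainder,
        relative_underestimate=rel,
    )
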