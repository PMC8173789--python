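"""Derivation of organ-specific SOC grading standards.

The subjective–objective-combined (SOC) standard for an organ at risk
is built from a cohort of cases that each carry the five geometric
indexes and an expert's subjective level (1–4). Per organ and index:

* If every case in the cohort received the same subjective level (a
  *single-level* organ), only one index range can be anchored in data.
  The observed extreme facing the missing adjacent levels becomes the
  boundary and the interval is extended to the theoretical limit on
  the level's own quality side: for a good level (3 or 4), DSC spans
  [observed min, 1] and distances span [0, observed max]; for the
  worst level (1), DSC spans [0, observed max] and distances
  [observed min, ∞).
* If several levels occur (*multi-level* organ), each pair of adjacent
  observed levels is compared. Disjoint observed [min, max] intervals
  become range-based standards directly. Overlapping intervals fall
  back to the per-level mean values, provided the means are monotone
  in the index's direction of improvement; otherwise the entry is
  marked undefined rather than silently reporting an unusable
  standard. A mixed outcome (ranges between one pair of levels, means
  between another) is legitimate and preserved per level.

Although the derivation works for any of the five indexes, DSC is the
recommended headline index: the grading helpers that consume a derived
standard default to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry_metrics import INDEX_DIRECTION, INDEX_NAMES, MetricSet


class DerivationError(ValueError):
    pass


@dataclass(frozen=True)
class CaseRecord:
    """One patient × organ case: metrics plus the expert's subjective level."""

    patient_id: str
    oar: str
    metrics: MetricSet
    subjective_level: int
    exclude: bool = False

    def __post_init__(self) -> None:
        if self.subjective_level not in (1, 2, 3, 4):
            raise DerivationError(
                f"subjective_level must be 1–4, got {self.subjective_level}"
            )


@dataclass(frozen=True)
class LevelStats:
    """Per-index min/max/mean of the cases at one subjective level."""

    level: int
    n_cases: int
    stats: Mapping[str, tuple[float, float, float]]  # index -> (min, max, mean)

    def minimum(self, index: str) -> float:
        return self.stats[index][0]

    def maximum(self, index: str) -> float:
        return self.stats[index][1]

    def mean(self, index: str) -> float:
        return self.stats[index][2]


@dataclass(frozen=True)
class StandardEntry:
    """The grading standard for one index at one level.

    ``mode`` is "range" (use ``low``/``high``; ``high=None`` encodes an
    interval unbounded above), "mean" (use ``mean`` as the level's
    representative value), or "undefined" (overlapping ranges with
    non-monotone means; no usable standard).
    """

    mode: str  # "range" | "mean" | "undefined"
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    n_cases: int = 0


@dataclass
class SOCStandard:
    """Derived grading standard for one organ.

    ``entries`` maps index name -> level -> StandardEntry; levels with
    no observed cases are simply absent.
    """

    oar: str
    distribution_kind: str  # "single-level" | "multi-level"
    entries: dict[str, dict[int, StandardEntry]] = field(default_factory=dict)

    def levels(self, index: str = "dsc") -> tuple[int, ...]:
        return tuple(sorted(self.entries.get(index, {})))

    def to_dict(self) -> dict:
        return {
            "oar": self.oar,
            "distribution_kind": self.distribution_kind,
            "entries": {
                index: {
                    str(level): {
                        "mode": e.mode, "low": e.low, "high": e.high,
                        "mean": e.mean, "n_cases": e.n_cases,
                    }
                    for level, e in by_level.items()
                }
                for index, by_level in self.entries.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOCStandard":
        std = cls(oar=d["oar"], distribution_kind=d["distribution_kind"])
        for index, by_level in d["entries"].items():
            std.entries[index] = {
                int(level): StandardEntry(**e) for level, e in by_level.items()
            }
        return std


def summarize_levels(cases: Sequence[CaseRecord]) -> list[LevelStats]:
    """Group one organ's cases by subjective level; exact per-index stats."""
    kept = [c for c in cases if not c.exclude]
    if not kept:
        raise DerivationError("no (non-excluded) cases to summarize")
    oars = {c.oar for c in kept}
    if len(oars) > 1:
        raise DerivationError(f"cases mix several organs: {sorted(oars)}")
    out = []
    for level in sorted({c.subjective_level for c in kept}):
        group = [c for c in kept if c.subjective_level == level]
        stats = {}
        for index in INDEX_NAMES:
            values = np.array([c.metrics.value(index) for c in group], dtype=float)
            stats[index] = (float(values.min()), float(values.max()), float(values.mean()))
        out.append(LevelStats(level=level, n_cases=len(group), stats=stats))
    return out


def ranges_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff the closed intervals intersect (shared endpoints count)."""
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    if a_lo > a_hi or b_lo > b_hi:
        raise DerivationError("interval bounds out of order")
    return a_lo <= b_hi and b_lo <= a_hi


def _half_bounded_entry(index: str, level: int, stats: LevelStats) -> StandardEntry:
    """Single-level organ: anchor at the extreme facing the absent levels."""
    good_side = level >= 2
    if INDEX_DIRECTION[index] == "higher":
        if good_side:
            return StandardEntry("range", low=stats.minimum(index), high=1.0,
                                 mean=stats.mean(index), n_cases=stats.n_cases)
        return StandardEntry("range", low=0.0, high=stats.maximum(index),
                             mean=stats.mean(index), n_cases=stats.n_cases)
    if good_side:
        return StandardEntry("range", low=0.0, high=stats.maximum(index),
                             mean=stats.mean(index), n_cases=stats.n_cases)
    return StandardEntry("range", low=stats.minimum(index), high=None,
                         mean=stats.mean(index), n_cases=stats.n_cases)


def _means_monotone(index: str, lower: LevelStats, upper: LevelStats) -> bool:
    """Do the level means improve from the worse to the better level?"""
    if INDEX_DIRECTION[index] == "higher":
        return lower.mean(index) < upper.mean(index)
    return lower.mean(index) > upper.mean(index)


def derive_soc_standard(
    cases: Sequence[CaseRecord], indexes: Iterable[str] = INDEX_NAMES
) -> SOCStandard:
    """Derive the SOC standard for one organ from its case cohort."""
    per_level = summarize_levels(cases)
    oar = next(c.oar for c in cases if not c.exclude)
    kind = "single-level" if len(per_level) == 1 else "multi-level"
    standard = SOCStandard(oar=oar, distribution_kind=kind)
    by_level = {s.level: s for s in per_level}
    levels = sorted(by_level)
    for index in indexes:
        if index not in INDEX_NAMES:
            raise DerivationError(f"unknown index {index!r}")
        entries: dict[int, StandardEntry] = {}
        if kind == "single-level":
            only = per_level[0]
            entries[only.level] = _half_bounded_entry(index, only.level, only)
        else:
            # adjacency in the observed sequence: pair consecutive levels
            pair_overlaps = {}
            for lo, hi in zip(levels, levels[1:]):
                pair_overlaps[(lo, hi)] = ranges_overlap(
                    (by_level[lo].minimum(index), by_level[lo].maximum(index)),
                    (by_level[hi].minimum(index), by_level[hi].maximum(index)),
                )
            for level in levels:
                stats = by_level[level]
                neighbor_pairs = [p for p in pair_overlaps if level in p]
                if not any(pair_overlaps[p] for p in neighbor_pairs):
                    entries[level] = StandardEntry(
                        "range", low=stats.minimum(index), high=stats.maximum(index),
                        mean=stats.mean(index), n_cases=stats.n_cases,
                    )
                    continue
                overlapping = [p for p in neighbor_pairs if pair_overlaps[p]]
                monotone = all(
                    _means_monotone(index, by_level[lo], by_level[hi])
                    for lo, hi in overlapping
                )
                if monotone:
                    entries[level] = StandardEntry(
                        "mean", mean=stats.mean(index), n_cases=stats.n_cases,
                    )
                else:
                    entries[level] = StandardEntry("undefined", n_cases=stats.n_cases)
        standard.entries[index] = entries
    return standard


def grade_by_standard(standard: SOCStandard, value: float, index: str = "dsc") -> int:
    """Assign a level to an index value under a derived range-based standard.

    Values falling in the unobserved gap between adjacent range-based
    intervals are assigned the worse level (conservative: borderline
    contours get flagged for more review, not less). Values beyond the
    observed extremes clamp to the nearest observed level. Mean-based
    or undefined entries cannot partition the axis and raise.
    """
    entries = standard.entries.get(index)
    if not entries:
        raise DerivationError(f"standard for {standard.oar!r} lacks index {index!r}")
    if any(e.mode != "range" for e in entries.values()):
        raise DerivationError(
            f"standard for {standard.oar!r}/{index} is not range-based throughout"
        )
    higher_better = INDEX_DIRECTION[index] == "higher"
    # order levels from worst to best along the value axis
    levels = sorted(entries)
    intervals = []
    for level in levels:
        e = entries[level]
        lo = -math.inf if e.low is None else e.low
        hi = math.inf if e.high is None else e.high
        intervals.append((level, lo, hi))
    for level, lo, hi in intervals:
        if lo <= value <= hi:
            return level
    # in a gap or outside: walk levels best-to-worst, return the worst level
    # whose interval the value has not surpassed in the improvement direction
    if higher_better:
        eligible = [lvl for lvl, lo, hi in intervals if value >= lo]
        return max(eligible) if eligible else min(levels)
    eligible = [lvl for lvl, lo, hi in intervals if value <= hi]
    return max(eligible) if eligible else min(levels)


# ---------------------------------------------------------------------------
# Rendering


def _fmt(x: float, index: str) -> str:
    # volume differences print as whole percents, distances/DSC with 2 decimals
    if index == "dv":
        return f"{x:g}"
    return f"{x:.2f}"


def format_entry(entry: StandardEntry, index: str) -> str:
    """Render one entry in the conventional report style."""
    if entry.mode == "undefined":
        return "undefined"
    if entry.mode == "mean":
        return _fmt(entry.mean, index)
    lo, hi = entry.low, entry.high
    if hi is None:
        return f"≥ {_fmt(lo, index)}"
    if lo == 0.0:
        return f"0–{_fmt(hi, index)}"
    if hi == 1.0 and INDEX_DIRECTION[index] == "higher":
        return f"{_fmt(lo, index)}–1"
    return f"{_fmt(lo, index)}–{_fmt(hi, index)}"


def format_standard_table(
    standards: Sequence[SOCStandard],
    indexes: Iterable[str] = INDEX_NAMES,
    levels: Sequence[int] = (1, 2, 3),
) -> str:
    """Tabular report: one row per organ, columns per index × level.

    Absent levels render as "–". Rows are ordered by descending mean
    DSC of the observed levels, ties broken by organ name, so the
    best-segmented organs come first.
    """
    indexes = [i for i in INDEX_NAMES if i in set(indexes)]
    header = ["Structure"] + [f"{idx.upper()} L{lvl}" for idx in indexes for lvl in levels]

    def sort_key(std: SOCStandard):
        dsc_entries = std.entries.get("dsc", {})
        means = [e.mean for e in dsc_entries.values() if e.mean is not None]
        return (-(sum(means) / len(means)) if means else 0.0, std.oar)

    lines = ["\t".join(header)]
    for std in sorted(standards, key=sort_key):
        row = [std.oar]
        for idx in indexes:
            by_level = std.entries.get(idx, {})
            for lvl in levels:
                row.append(format_entry(by_level[lvl], idx) if lvl in by_level else "–")
        lines.append("\t".join(row))
    return "\n".join(lines)
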