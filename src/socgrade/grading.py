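"""Objective and subjective grading of auto-segmentation accuracy.

Objective path: a *grading scheme* maps each geometric index value to a
level in 1..4 through ordered threshold intervals. Three schemes ship
with the package:

``our_center``
    four levels on all five indexes; Level 4 is reserved for the exact
    perfect value (DSC 1, distance 0) — auto-segmentation that can
    completely replace manual delineation.
``velker``
    three levels on DSC only (poor / medium / good).
``ciardo``
    three levels on DSC, centroid distance and average Hausdorff
    distance.

Boundary convention: a value lying exactly on a cutpoint is assigned
the *better* of the two adjacent levels (intervals are closed on the
side of better quality). Improving an index value therefore never
lowers the level.

Subjective path: an expert reviews the auto-contour slice by slice and
records how many CT slices need modification. The grade depends on the
organ's length class: organs longer than 10 slices are graded on the
percentage of slices to modify, organs of 3–10 slices on the modified
slice count, and organs shorter than 3 slices on a stricter count
scale. Zero modified slices is always Level 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .geometry_metrics import INDEX_NAMES, MetricSet

PERFECT_TOL = 1e-9

BUILTIN_SCHEMES = ("our_center", "velker", "ciardo")


class GradingError(ValueError):
    pass


class UnsupportedIndexError(GradingError):
    """The scheme does not define thresholds for the requested index."""


@dataclass(frozen=True)
class IndexThresholds:
    """Threshold intervals mapping one index's values to levels.

    ``cutpoints = (c1, c2)`` split the legal range into three levels;
    ``perfect`` (if present) defines Level 4 at exactly that value.
    For a higher-is-better index (DSC): Level 1 = [0, c1), 2 = [c1, c2),
    3 = [c2, 1]. For lower-is-better: Level 3 = [0, c1], 2 = (c1, c2],
    1 = (c2, ∞).
    """

    index_name: str
    direction: str  # "higher" | "lower"
    cutpoints: tuple[float, float]
    perfect: float | None = None

    def __post_init__(self) -> None:
        if self.index_name not in INDEX_NAMES:
            raise GradingError(f"unknown index {self.index_name!r}")
        if self.direction not in ("higher", "lower"):
            raise GradingError(f"direction must be 'higher' or 'lower', got {self.direction!r}")
        c1, c2 = self.cutpoints
        if not c1 < c2:
            raise GradingError(f"cutpoints must be strictly increasing, got {self.cutpoints}")

    @property
    def levels(self) -> tuple[int, ...]:
        """Levels this index can produce under the scheme."""
        return (1, 2, 3, 4) if self.perfect is not None else (1, 2, 3)


@dataclass(frozen=True)
class GradingScheme:
    """A named set of per-index thresholds."""

    name: str
    thresholds: Mapping[str, IndexThresholds]
    statistic: str = "mean"

    @property
    def indexes(self) -> tuple[str, ...]:
        return tuple(i for i in INDEX_NAMES if i in self.thresholds)

    def __getitem__(self, index: str) -> IndexThresholds:
        try:
            return self.thresholds[index]
        except KeyError:
            raise UnsupportedIndexError(
                f"scheme {self.name!r} defines no thresholds for index {index!r}"
            ) from None


def scheme_from_dict(cfg: dict) -> GradingScheme:
    """Build and validate a scheme from its JSON/dict configuration."""
    if "name" not in cfg or "indexes" not in cfg or not isinstance(cfg["indexes"], dict):
        raise GradingError("scheme config requires 'name' and a mapping under 'indexes'")
    thresholds = {}
    for index, spec in cfg["indexes"].items():
        thresholds[index] = IndexThresholds(
            index_name=index,
            direction=spec["direction"],
            cutpoints=tuple(float(c) for c in spec["cutpoints"]),
            perfect=None if spec.get("perfect") is None else float(spec["perfect"]),
        )
    return GradingScheme(
        name=str(cfg["name"]), thresholds=thresholds, statistic=cfg.get("statistic", "mean")
    )


def load_scheme(name_or_path: str | Path) -> GradingScheme:
    """Load a built-in scheme by name, or a custom scheme from a JSON file."""
    name = str(name_or_path)
    if name in BUILTIN_SCHEMES:
        text = resources.files("socgrade.schemes").joinpath(f"{name}.json").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise GradingError(
                f"unknown scheme {name!r}: not a built-in ({', '.join(BUILTIN_SCHEMES)}) "
                "and no such file"
            )
        text = path.read_text()
    return scheme_from_dict(json.loads(text))


def grade_value(value: float, thresholds: IndexThresholds) -> int:
    """Map one index value to a level under the given thresholds."""
    c1, c2 = thresholds.cutpoints
    if thresholds.direction == "higher":
        if not 0.0 <= value <= 1.0 + PERFECT_TOL:
            raise GradingError(f"{thresholds.index_name} value {value} outside [0, 1]")
        if thresholds.perfect is not None and abs(value - thresholds.perfect) <= PERFECT_TOL:
            return 4
        if value >= c2:
            return 3
        if value >= c1:
            return 2
        return 1
    if value < 0:
        raise GradingError(f"{thresholds.index_name} value {value} is negative")
    if thresholds.perfect is not None and abs(value - thresholds.perfect) <= PERFECT_TOL:
        return 4
    if value <= c1:
        return 3
    if value <= c2:
        return 2
    return 1


def grade_metric_set(metrics: MetricSet, scheme: GradingScheme) -> dict[str, int]:
    """One level per index the scheme defines; other indexes are omitted."""
    return {index: grade_value(metrics.value(index), scheme[index]) for index in scheme.indexes}


# ---------------------------------------------------------------------------
# Subjective path


@dataclass(frozen=True)
class SubjectiveRecord:
    """Slice-review outcome for one organ-at-risk case.

    ``pct_modified`` may be supplied directly (e.g. an average of
    per-patient percentages); otherwise it is computed from the counts.
    """

    oar: str
    total_slices: float
    modified_slices: float | None = None
    pct_modified: float | None = None

    def __post_init__(self) -> None:
        if self.total_slices < 0:
            raise GradingError("total_slices must be nonnegative")
        if self.modified_slices is None and self.pct_modified is None:
            raise GradingError("record needs modified_slices or pct_modified")
        if self.modified_slices is not None:
            if self.modified_slices < 0:
                raise GradingError("modified_slices must be nonnegative")
            if self.modified_slices > self.total_slices:
                raise GradingError(
                    f"{self.oar}: modified_slices ({self.modified_slices}) exceeds "
                    f"total_slices ({self.total_slices})"
                )
            if self.total_slices == 0 and self.modified_slices > 0:
                raise GradingError(f"{self.oar}: modified slices with zero total slices")
        if self.pct_modified is not None and not 0.0 <= self.pct_modified <= 100.0:
            raise GradingError(f"pct_modified must lie in [0, 100], got {self.pct_modified}")

    @property
    def effective_pct(self) -> float:
        """Percentage used for grading: the supplied one, else 100·modified/total."""
        if self.pct_modified is not None:
            return float(self.pct_modified)
        if self.total_slices == 0:
            return 0.0
        return 100.0 * self.modified_slices / self.total_slices

    @property
    def effective_modified(self) -> float:
        if self.modified_slices is not None:
            return float(self.modified_slices)
        return self.pct_modified / 100.0 * self.total_slices


def subjective_grade(record: SubjectiveRecord) -> int:
    """Grade a slice-review record on the four-level subjective standard.

    Boundaries are closed on the better side, mirroring the objective
    convention (e.g. exactly 10% modified in a long organ is Level 3).
    """
    modified = record.effective_modified
    if modified == 0:
        return 4
    total = record.total_slices
    if total == 0:
        raise GradingError(f"{record.oar}: modified slices with zero total slices")
    if total > 10:
        pct = record.effective_pct
        if pct <= 10.0:
            return 3
        if pct <= 20.0:
            return 2
        return 1
    if total >= 3:
        if modified <= 1:
            return 3
        if modified <= 3:
            return 2
        return 1
    # organs shorter than 3 slices: stricter count scale
    if modified <= 1:
        return 3
    if modified <= 2:
        return 2
    return 1


def consistency_report(
    subjective_levels: Mapping[str, int], objective_levels: Mapping[str, int]
) -> dict:
    """Compare per-organ subjective levels with objective (index) levels.

    Returns per-organ deltas (subjective − objective) plus a summary
    counting organs where the subjective grade is exactly one level
    lower, equal, or anything else; percentages are of the organ total,
    rounded to one decimal.
    """
    sub_keys, obj_keys = set(subjective_levels), set(objective_levels)
    if sub_keys != obj_keys:
        missing = sorted(sub_keys ^ obj_keys)
        raise GradingError(f"organ sets differ between the two gradings: {missing}")
    rows = []
    counts = {"one_level_lower": 0, "equal": 0, "other": 0}
    for oar in subjective_levels:
        s, o = subjective_levels[oar], objective_levels[oar]
        delta = s - o
        if delta == -1:
            category = "one_level_lower"
        elif delta == 0:
            category = "equal"
        else:
            category = "other"
        counts[category] += 1
        rows.append({"oar": oar, "subjective": s, "objective": o,
                     "delta": delta, "category": category})
    total = len(rows)
    summary = {}
    for key, n in counts.items():
        summary[key] = n
        summary[f"pct_{key}"] = round(100.0 * n / total, 1) if total else 0.0
    summary["n_oars"] = total
    return {"per_oar": rows, "summary": summary}
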