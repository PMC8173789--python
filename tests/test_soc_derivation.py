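"""SOC standard derivation: level summaries, range/mean rule, rendering."""

import numpy as np
import pytest

from socgrade import (
    CaseRecord,
    CohortSpec,
    DerivationError,
    LevelSpec,
    MetricSet,
    derive_soc_standard,
    format_standard_table,
    grade_by_standard,
    ranges_overlap,
    simulate_cohort,
    summarize_levels,
)
from socgrade.soc_derivation import format_entry


def case(oar, level, dsc, patient="p", **kw):
    metrics = MetricSet(
        dsc=dsc,
        cmd_cm=kw.get("cmd", 0.2),
        dv_pct=kw.get("dv", 5.0),
        mhd_cm=kw.get("mhd", 1.0),
        ahd_cm=kw.get("ahd", 0.1),
    )
    return CaseRecord(patient, oar, metrics, level, exclude=kw.get("exclude", False))


class TestSummarizeLevels:
    def test_single_level_stats(self):
        dscs = [0.93, 0.94, 0.95, 0.97, 0.99]
        stats = summarize_levels([case("lung", 3, d, f"p{i}") for i, d in enumerate(dscs)])
        assert len(stats) == 1
        (s,) = stats
        assert s.level == 3 and s.n_cases == 5
        assert s.minimum("dsc") == 0.93
        assert s.maximum("dsc") == 0.99
        assert s.mean("dsc") == pytest.approx(0.956)

    def test_single_case_collapses(self):
        (s,) = summarize_levels([case("lung", 2, 0.8)])
        assert s.minimum("dsc") == s.maximum("dsc") == s.mean("dsc") == 0.8

    def test_grouping_by_level(self):
        stats = summarize_levels(
            [case("lung", 1, 0.5), case("lung", 1, 0.6), case("lung", 3, 0.9)]
        )
        assert [(s.level, s.n_cases) for s in stats] == [(1, 2), (3, 1)]

    def test_excluded_cases_dropped(self):
        stats = summarize_levels(
            [case("lung", 3, 0.9), case("lung", 3, 0.2, exclude=True)]
        )
        assert stats[0].n_cases == 1 and stats[0].minimum("dsc") == 0.9

    def test_errors(self):
        with pytest.raises(DerivationError):
            summarize_levels([])
        with pytest.raises(DerivationError, match="mix"):
            summarize_levels([case("lung", 3, 0.9), case("heart", 3, 0.9)])


class TestRangesOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0.88, 0.95), (0.95, 1.0), True),   # shared endpoint counts
            ((0.5, 0.6), (0.7, 0.8), False),
            ((0.1, 0.9), (0.2, 0.3), True),      # containment
        ],
    )
    def test_cases(self, a, b, expected):
        assert ranges_overlap(a, b) is expected
        assert ranges_overlap(b, a) is expected


class TestDeriveStandard:
    def test_single_good_level_half_bounded(self):
        cases = [case("lung", 3, d, cmd=c)
                 for d, c in [(0.93, 0.10), (0.95, 0.26), (0.98, 0.05)]]
        std = derive_soc_standard(cases)
        assert std.distribution_kind == "single-level"
        dsc_entry = std.entries["dsc"][3]
        assert (dsc_entry.mode, dsc_entry.low, dsc_entry.high) == ("range", 0.93, 1.0)
        cmd_entry = std.entries["cmd"][3]
        assert (cmd_entry.mode, cmd_entry.low, cmd_entry.high) == ("range", 0.0, 0.26)

    def test_single_bad_level_half_bounded(self):
        cases = [case("cw", 1, d, cmd=c, dv=30, mhd=4.0, ahd=0.5)
                 for d, c in [(0.70, 0.28), (0.85, 0.9)]]
        std = derive_soc_standard(cases)
        dsc_entry = std.entries["dsc"][1]
        assert (dsc_entry.mode, dsc_entry.low, dsc_entry.high) == ("range", 0.0, 0.85)
        cmd_entry = std.entries["cmd"][1]
        assert (cmd_entry.mode, cmd_entry.low, cmd_entry.high) == ("range", 0.28, None)

    def test_disjoint_levels_give_ranges(self):
        cases = (
            [case("aor", 2, d) for d in (0.70, 0.74, 0.78)]
            + [case("aor", 3, d) for d in (0.82, 0.90, 0.95)]
        )
        std = derive_soc_standard(cases, indexes=["dsc"])
        assert std.distribution_kind == "multi-level"
        e2, e3 = std.entries["dsc"][2], std.entries["dsc"][3]
        assert (e2.mode, e2.low, e2.high) == ("range", 0.70, 0.78)
        assert (e3.mode, e3.low, e3.high) == ("range", 0.82, 0.95)

    def test_overlapping_monotone_means_give_means(self):
        cases = (
            [case("heart", 2, d) for d in (0.70, 0.80, 0.90)]
            + [case("heart", 3, d) for d in (0.85, 0.91, 0.97)]
        )
        std = derive_soc_standard(cases, indexes=["dsc"])
        e2, e3 = std.entries["dsc"][2], std.entries["dsc"][3]
        assert e2.mode == e3.mode == "mean"
        assert e2.mean == pytest.approx(0.80)
        assert e3.mean == pytest.approx(0.91)

    def test_overlapping_nonmonotone_means_undefined(self):
        cases = (
            [case("x", 2, d) for d in (0.80, 0.95)]
            + [case("x", 3, d) for d in (0.78, 0.90)]  # worse mean at better level
        )
        std = derive_soc_standard(cases, indexes=["dsc"])
        assert std.entries["dsc"][2].mode == "undefined"
        assert std.entries["dsc"][3].mode == "undefined"

    def test_mixed_modes_across_pairs(self):
        # pair (1,2) disjoint, pair (2,3) overlapping with monotone means:
        # level 1 keeps its range, levels 2 and 3 fall back to means
        cases = (
            [case("mix", 1, d) for d in (0.40, 0.55)]
            + [case("mix", 2, d) for d in (0.70, 0.85)]
            + [case("mix", 3, d) for d in (0.80, 0.95)]
        )
        std = derive_soc_standard(cases, indexes=["dsc"])
        assert std.entries["dsc"][1].mode == "range"
        assert std.entries["dsc"][2].mode == "mean"
        assert std.entries["dsc"][3].mode == "mean"

    def test_levels_without_cases_absent(self):
        std = derive_soc_standard(
            [case("t", 1, 0.5), case("t", 2, 0.8)], indexes=["dsc"]
        )
        assert std.levels("dsc") == (1, 2)

    def test_round_trip_dict(self):
        std = derive_soc_standard([case("lung", 3, 0.9)], indexes=["dsc", "cmd"])
        from socgrade import SOCStandard

        back = SOCStandard.from_dict(std.to_dict())
        assert back.entries == std.entries
        assert back.distribution_kind == std.distribution_kind


class TestGradeByStandard:
    def test_self_consistency_on_disjoint_cohort(self, rng):
        intervals = {1: (0.30, 0.55), 2: (0.60, 0.78), 3: (0.82, 0.99)}
        cases = [
            case("org", level, rng.uniform(lo, hi), f"p{level}{i}")
            for level, (lo, hi) in intervals.items()
            for i in range(30)
        ]
        std = derive_soc_standard(cases, indexes=["dsc"])
        for c in cases:
            assert grade_by_standard(std, c.metrics.dsc) == c.subjective_level

    def test_gap_falls_to_worse_level(self):
        cases = [case("org", 2, d) for d in (0.60, 0.70)] + [
            case("org", 3, d) for d in (0.85, 0.95)
        ]
        std = derive_soc_standard(cases, indexes=["dsc"])
        assert grade_by_standard(std, 0.80) == 2  # inside the unobserved gap
        assert grade_by_standard(std, 0.99) == 3  # above all observed values
        assert grade_by_standard(std, 0.10) == 2  # below: clamps to worst observed

    def test_mean_based_standard_refuses_to_grade(self):
        cases = [case("h", 2, d) for d in (0.7, 0.9)] + [
            case("h", 3, d) for d in (0.8, 0.95)
        ]
        std = derive_soc_standard(cases, indexes=["dsc"])
        with pytest.raises(DerivationError):
            grade_by_standard(std, 0.85)


class TestParameterRecovery:
    """Simulated cohorts with known per-level structure are recovered."""

    def test_disjoint_intervals_recovered_at_n200(self):
        intervals = {1: (0.35, 0.55), 2: (0.62, 0.76), 3: (0.84, 0.98)}
        spec = CohortSpec(
            oars={"org": {lvl: LevelSpec(n=200, low=lo, high=hi)
                          for lvl, (lo, hi) in intervals.items()}},
            seed=7,
        )
        std = derive_soc_standard(simulate_cohort(spec), indexes=["dsc"])
        # max-order-statistic tolerance: expected endpoint gap ~ width/(n+1)
        for lvl, (lo, hi) in intervals.items():
            entry = std.entries["dsc"][lvl]
            assert entry.mode == "range"
            tol = 6 * (hi - lo) / 201
            assert entry.low == pytest.approx(lo, abs=tol)
            assert entry.high == pytest.approx(hi, abs=tol)

    def test_overlapping_means_recovered_within_3_se(self):
        n, sd = 200, 0.06
        means = {2: 0.78, 3: 0.88}
        spec = CohortSpec(
            oars={"org": {lvl: LevelSpec(n=n, mean=m, sd=sd) for lvl, m in means.items()}},
            seed=11,
        )
        std = derive_soc_standard(simulate_cohort(spec), indexes=["dsc"])
        for lvl, m in means.items():
            entry = std.entries["dsc"][lvl]
            assert entry.mode == "mean"
            assert abs(entry.mean - m) <= 3 * sd / np.sqrt(n)

    def test_distribution_kind_matches_level_count(self):
        single = derive_soc_standard([case("a", 3, 0.9), case("a", 3, 0.95)])
        multi = derive_soc_standard([case("b", 2, 0.7), case("b", 3, 0.9)])
        assert single.distribution_kind == "single-level"
        assert multi.distribution_kind == "multi-level"


class TestFormatting:
    def test_half_bounded_rendering(self):
        good = derive_soc_standard(
            [case("lung", 3, 0.93, cmd=0.26, dv=14, mhd=4.27, ahd=0.19)]
        )
        row = format_standard_table([good]).splitlines()[1].split("\t")
        assert row[0] == "lung"
        assert "0.93–1" in row and "0–0.26" in row and "0–14" in row

    def test_worst_level_distance_rendering(self):
        bad = derive_soc_standard([case("cw", 1, 0.7, cmd=0.28, dv=30, mhd=4, ahd=0.5)])
        assert format_entry(bad.entries["cmd"][1], "cmd") == "≥ 0.28"
        assert format_entry(bad.entries["dsc"][1], "dsc") == "0–0.70"

    def test_absent_level_renders_dash(self):
        std = derive_soc_standard([case("t", 1, 0.5), case("t", 2, 0.8)], indexes=["dsc"])
        table = format_standard_table([std], indexes=["dsc"])
        assert table.splitlines()[1].split("\t")[3] == "–"  # level 3 column

    def test_mean_entries_render_bare_numbers(self):
        cases = [case("h", 2, d) for d in (0.7, 0.9)] + [
            case("h", 3, d) for d in (0.8, 0.95)
        ]
        std = derive_soc_standard(cases, indexes=["dsc"])
        cells = format_standard_table([std], indexes=["dsc"]).splitlines()[1].split("\t")
        assert cells[2] == "0.80" and cells[3] == "0.88"

    def test_rows_ordered_by_descending_mean_dsc(self):
        best = derive_soc_standard([case("best", 3, 0.95)], indexes=["dsc"])
        worst = derive_soc_standard([case("worst", 1, 0.55)], indexes=["dsc"])
        lines = format_standard_table([worst, best], indexes=["dsc"]).splitlines()
        assert lines[1].startswith("best") and lines[2].startswith("worst")
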