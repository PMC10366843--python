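"""Accuracies, Fisher's exact test, the evaluation table, and timings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cowlabel import (
    CANONICAL_SEGMENTS,
    ContingencyTable2x2,
    InputError,
    UndefinedAccuracyError,
    accuracy_percent,
    build_evaluation_table,
    evaluation_table_from_counts,
    fisher_exact_two_sided,
    format_p_value,
    time_methods,
    undetected_percent,
)
from cowlabel.datasets import example_cohort_counts


class TestAccuracy:
    @pytest.mark.parametrize(
        "correct,incorrect,expected",
        [(614, 121, 83.5), (714, 21, 97.1), (706, 29, 96.1), (19, 25, 43.2)],
    )
    def test_reported_to_one_decimal(self, correct, incorrect, expected):
        assert accuracy_percent(correct, incorrect) == expected

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedAccuracyError):
            accuracy_percent(0, 0)

    @pytest.mark.parametrize(
        "undetected,subjects,expected", [(16, 60, 26.7), (46, 60, 76.7), (42, 60, 70.0), (0, 60, 0.0)]
    )
    def test_undetected_percent(self, undetected, subjects, expected):
        assert undetected_percent(undetected, subjects) == expected

    def test_undetected_zero_subjects_rejected(self):
        with pytest.raises(InputError):
            undetected_percent(1, 0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected_3dp",
        [
            ([[44, 0], [36, 8]], 0.006),
            ([[58, 2], [60, 0]], 0.496),
            ([[51, 9], [50, 10]], 1.0),
            ([[8, 6], [14, 0]], 0.016),
            ([[51, 9], [60, 0]], 0.003),
            ([[30, 5], [30, 5]], 1.0),
        ],
    )
    def test_reference_tables(self, table, expected_3dp):
        assert round(fisher_exact_two_sided(table), 3) == expected_3dp

    def test_extreme_table_below_printing_threshold(self):
        assert fisher_exact_two_sided([[19, 25], [44, 0]]) < 0.0005

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    def test_matches_scipy_and_is_symmetric(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(stats.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-7)
        assert p == pytest.approx(fisher_exact_two_sided([[c, d], [a, b]]), rel=1e-12)
        assert p == pytest.approx(fisher_exact_two_sided([[b, a], [d, c]]), rel=1e-12)

    def test_agrees_with_enumeration_oracle_up_to_n200(self):
        # oracle: enumerate every table with the observed margins and sum
        # the hypergeometric point masses no greater than the observed one
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 201))
            r1 = int(rng.integers(1, n))
            c1 = int(rng.integers(1, n))
            lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
            a = int(rng.integers(lo, hi + 1))
            table = [[a, r1 - a], [c1 - a, n - r1 - (c1 - a)]]
            pmf = stats.hypergeom(n, c1, r1).pmf(np.arange(lo, hi + 1))
            p_obs = stats.hypergeom(n, c1, r1).pmf(a)
            oracle = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
            assert fisher_exact_two_sided(table) == pytest.approx(min(oracle, 1.0), rel=1e-9)

    def test_equal_margins_extremal_table_doubles_one_tail(self):
        # equal-size groups, observed table maximally extremal: the two
        # tails are mirror images, so p is twice the one-tail sum
        for n_half in range(2, 21):
            table = [[n_half, 0], [0, n_half]]
            n, c1, r1 = 2 * n_half, n_half, n_half
            one_tail = stats.hypergeom(n, c1, r1).pmf(n_half)
            assert fisher_exact_two_sided(table) == pytest.approx(
                min(2 * one_tail, 1.0), rel=1e-9
            )

    def test_invalid_tables_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(InputError):
            ContingencyTable2x2(-1, 1, 1, 1)
        with pytest.raises(InputError):
            fisher_exact_two_sided([[1, 2, 3], [4, 5, 6]])


class TestFormatting:
    @pytest.mark.parametrize(
        "p,rendered",
        [(0.0004, "<0.001"), (0.0006, "0.001"), (0.0055, "0.006"),
         (0.4958, "0.496"), (0.99951, "1"), (1.0, "1")],
    )
    def test_p_value_rendering(self, p, rendered):
        assert format_p_value(p) == rendered


class TestEvaluationTable:
    def test_example_cohort_reproduces_totals(self):
        table = evaluation_table_from_counts(example_cohort_counts())
        totals = table.data.loc["Total"]
        assert (totals["dfs_correct"], totals["dfs_incorrect"]) == (614, 121)
        assert (totals["dijkstra_correct"], totals["dijkstra_incorrect"]) == (714, 21)
        assert (totals["astar_correct"], totals["astar_incorrect"]) == (706, 29)
        assert totals["undetected"] == 105
        assert totals["total"] == 840
        assert table.accuracy("dfs") == 83.5
        assert table.accuracy("dijkstra") == 97.1
        assert table.accuracy("astar") == 96.1
        assert table.accuracy("dfs", "AComm") == 43.2

    def test_example_cohort_p_values(self):
        table = evaluation_table_from_counts(example_cohort_counts())
        assert round(table.p_value("dijkstra", "astar", "AComm"), 3) == 0.006
        assert round(table.p_value("dfs", "dijkstra", "R-PComm"), 3) == 0.016
        assert round(table.p_value("dfs", "dijkstra", "R-A1"), 3) == 0.003
        assert round(table.p_value("dfs", "dijkstra", "L-M1"), 3) == 0.496
        assert round(table.p_value("dfs", "dijkstra", "R-ICA"), 3) == 1.0
        assert table.p_value("dfs", "dijkstra", "AComm") < 0.001

    def test_conservation_identities(self):
        table = evaluation_table_from_counts(example_cohort_counts())
        segs = table.data.drop(index="Total")
        for m in ("dfs", "dijkstra", "astar"):
            np.testing.assert_array_equal(
                segs[f"{m}_correct"] + segs[f"{m}_incorrect"] + segs["undetected"],
                segs["total"],
            )
        np.testing.assert_array_equal(
            segs.drop(columns=[c for c in segs if c.startswith("p_")]).sum(),
            table.data.loc["Total"].drop([c for c in segs if c.startswith("p_")]),
        )

    def test_mismatched_cohorts_rejected(self):
        counts = example_cohort_counts()
        counts.loc["AComm", "dfs_correct"] += 1  # breaks the shared total
        with pytest.raises(InputError, match="totals differ"):
            evaluation_table_from_counts(counts)

    def test_missing_method_column_rejected(self):
        counts = example_cohort_counts().drop(columns=["astar_correct"])
        with pytest.raises(InputError, match="astar_correct"):
            evaluation_table_from_counts(counts)

    def test_csv_render_uses_report_formatting(self, tmp_path):
        table = evaluation_table_from_counts(example_cohort_counts())
        p = tmp_path / "table.csv"
        table.to_csv(p)
        text = p.read_text()
        assert "<0.001" in text
        assert "0.496" in text


def _synthetic_runs(n_subjects=20, seed=3):
    """A phantom-style cohort: statuses and correctness per method/subject."""
    rng = np.random.default_rng(seed)
    runs = {m: [] for m in ("dfs", "dijkstra", "astar")}
    correctness = {m: [] for m in ("dfs", "dijkstra", "astar")}
    for _ in range(n_subjects):
        undetected = {s for s in CANONICAL_SEGMENTS if rng.random() < 0.1}
        for m in runs:
            status = {
                s: "undetected" if s in undetected else "found" for s in CANONICAL_SEGMENTS
            }
            correct = {
                s: bool(rng.random() > (0.3 if m == "dfs" else 0.05))
                for s in CANONICAL_SEGMENTS
                if status[s] == "found"
            }
            runs[m].append(status)
            correctness[m].append(correct)
    return runs, correctness


class TestBuildFromRuns:
    def test_per_segment_conservation_over_cohort(self):
        runs, correctness = _synthetic_runs(n_subjects=20)
        table = build_evaluation_table(runs, correctness)
        segs = table.data.drop(index="Total")
        assert (segs["total"] == 20).all()

    def test_single_method_input_rejected(self):
        runs, correctness = _synthetic_runs(n_subjects=3)
        with pytest.raises(InputError, match="methods"):
            build_evaluation_table({"dfs": runs["dfs"]}, {"dfs": correctness["dfs"]})

    def test_cohort_size_mismatch_rejected(self):
        runs, correctness = _synthetic_runs(n_subjects=3)
        runs["astar"] = runs["astar"][:2]
        with pytest.raises(InputError, match="cohort"):
            build_evaluation_table(runs, correctness)


class TestTiming:
    def test_reports_positive_timings_and_bounded_graph_fraction(
        self, pipeline_complete, phantom_complete
    ):
        df = time_methods(
            pipeline_complete.graph,
            pipeline_complete.skeleton,
            list(phantom_complete.specs),
            repetitions=2,
        )
        assert set(df.index) == {"dfs", "dijkstra", "astar"}
        assert (df["pathfind_mean_ms"] > 0).all()
        assert ((df["graph_fraction"] > 0) & (df["graph_fraction"] < 1)).all()
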