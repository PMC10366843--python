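"""Method-comparison statistics: accuracies, Fisher's exact tests, timings.

The evaluation mirrors a standard method-comparison design: for each vessel
segment, each path-finding method yields a number of correct and incorrect
paths over a cohort of subjects (a path is "correct" when it follows the
intended vessel; on phantoms this is judged against ground-truth
centerlines, on real data by a reviewer). Segments whose vessel was absent
from the binary mask are "undetected" and excluded from accuracy
denominators. Differences between methods are tested per segment with a
two-sided Fisher's exact test on the 2x2 correct/incorrect table.

The Fisher test uses the minimum-likelihood two-sided convention: with the
table margins fixed, the p-value is the sum of hypergeometric point
probabilities of every table no more probable than the observed one (with
1e-7 relative slack absorbing floating-point noise). Point probabilities
are computed with log-factorials, so cohorts of hundreds of subjects do not
overflow.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from math import inf, lgamma
from statistics import mean, stdev

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedAccuracyError
from .volume_io import CANONICAL_SEGMENTS

__all__ = [
    "METHODS",
    "ContingencyTable2x2",
    "accuracy_percent",
    "undetected_percent",
    "fisher_exact_two_sided",
    "format_p_value",
    "EvaluationTable",
    "build_evaluation_table",
    "evaluation_table_from_counts",
    "time_methods",
]

#: The three compared path-finding methods, in report column order.
METHODS: tuple[str, ...] = ("dfs", "dijkstra", "astar")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): row 1 = method X correct/incorrect, row 2 = method Y."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in vals):
            raise InputError(f"table entries must be non-negative integers, got {vals}")
        if sum(vals) == 0:
            raise InputError("contingency table is all zeros")


def _round1(x: float) -> float:
    """Round to one decimal, halves away from zero (report convention)."""
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    )


def accuracy_percent(correct: int, incorrect: int) -> float:
    """Percentage of correct paths among found paths, to one decimal."""
    denom = correct + incorrect
    if denom <= 0:
        raise UndefinedAccuracyError("accuracy undefined: no found paths")
    return _round1(100.0 * correct / denom)


def undetected_percent(undetected: int, subjects: int) -> float:
    """Percentage of subjects in which the vessel was undetected, to one decimal."""
    if subjects <= 0:
        raise InputError(f"subjects must be positive, got {subjects}")
    if undetected < 0 or undetected > subjects:
        raise InputError(f"undetected must be within [0, {subjects}], got {undetected}")
    return _round1(100.0 * undetected / subjects)


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable2x2` or any 2x2 array-like
    ``[[a, b], [c, d]]``. The p-value sums the hypergeometric point
    probabilities (margins fixed) of all tables whose probability does not
    exceed the observed table's, with 1e-7 relative slack.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise InputError(f"expected a 2x2 table, got shape {arr.shape}")
        (a, b), (c, d) = arr.tolist()
        t = ContingencyTable2x2(a, b, c, d)  # validates integrality
        a, b, c, d = int(t.a), int(t.b), int(t.c), int(t.d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logpmf(k: int) -> float:
        return _log_binom(r1, k) + _log_binom(r2, c1 - k) - _log_binom(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = logpmf(a)
    # sum point probabilities <= observed * (1 + 1e-7), in probability space
    p = 0.0
    for k in range(lo, hi + 1):
        lp = logpmf(k)
        if lp <= log_obs + 1e-7:  # log(1 + 1e-7) ~ 1e-7
            p += float(np.exp(lp))
    return min(p, 1.0)


def format_p_value(p: float) -> str:
    """Render a p-value the way method-comparison tables print it."""
    import decimal

    if p < 0.0005:
        return "<0.001"
    q = decimal.Decimal(repr(float(p))).quantize(
        decimal.Decimal("0.001"), rounding=decimal.ROUND_HALF_UP
    )
    if q >= 1:
        return "1"
    return str(q)


_PAIRS = (("dfs", "dijkstra"), ("dfs", "astar"), ("dijkstra", "astar"))


@dataclass(frozen=True)
class EvaluationTable:
    """Per-segment counts, pairwise Fisher p-values, and a totals row.

    ``data`` has one row per canonical segment plus a ``Total`` row, with
    columns ``{method}_correct``, ``{method}_incorrect`` for each method,
    ``undetected``, ``total``, and ``p_{x}_vs_{y}`` for the three method
    pairs (NaN in the totals row).
    """

    data: pd.DataFrame

    def accuracy(self, method: str, segment: str = "Total") -> float:
        row = self.data.loc[segment]
        return accuracy_percent(int(row[f"{method}_correct"]), int(row[f"{method}_incorrect"]))

    def p_value(self, method_x: str, method_y: str, segment: str) -> float:
        return float(self.data.loc[segment, f"p_{method_x}_vs_{method_y}"])

    def formatted(self) -> pd.DataFrame:
        """Copy with p-value columns rendered as report strings."""
        out = self.data.copy()
        for x, y in _PAIRS:
            col = f"p_{x}_vs_{y}"
            out[col] = [
                "" if np.isnan(p) else format_p_value(p) for p in self.data[col]
            ]
        return out

    def to_csv(self, path) -> None:
        self.formatted().to_csv(path, index=True, index_label="segment")

    def to_json(self, path) -> None:
        self.data.to_json(path, orient="index", indent=1)


def evaluation_table_from_counts(counts: pd.DataFrame) -> EvaluationTable:
    """Build the evaluation table from per-segment aggregated counts.

    ``counts`` is indexed by the 14 canonical segment names with columns
    ``{method}_correct``, ``{method}_incorrect`` (for dfs, dijkstra, astar)
    and ``undetected``. Per-segment totals must agree across methods
    (correct + incorrect + undetected is the cohort size).
    """
    counts = counts.copy()
    missing = [s for s in CANONICAL_SEGMENTS if s not in counts.index]
    if missing:
        raise InputError(f"counts missing segments: {missing}")
    needed = [f"{m}_{k}" for m in METHODS for k in ("correct", "incorrect")] + ["undetected"]
    for col in needed:
        if col not in counts.columns:
            raise InputError(f"counts missing column {col!r}")
    counts = counts.loc[list(CANONICAL_SEGMENTS), needed].astype(int)

    totals_per_method = {
        m: counts[f"{m}_correct"] + counts[f"{m}_incorrect"] + counts["undetected"]
        for m in METHODS
    }
    ref = totals_per_method[METHODS[0]]
    for m in METHODS[1:]:
        if not (totals_per_method[m] == ref).all():
            raise InputError(
                f"per-segment totals differ between {METHODS[0]} and {m}; "
                "all methods must be evaluated on the same cohort"
            )
    counts["total"] = ref

    for x, y in _PAIRS:
        counts[f"p_{x}_vs_{y}"] = [
            fisher_exact_two_sided(
                [
                    [row[f"{x}_correct"], row[f"{x}_incorrect"]],
                    [row[f"{y}_correct"], row[f"{y}_incorrect"]],
                ]
            )
            for _, row in counts.iterrows()
        ]

    totals = counts.select_dtypes("number").sum()
    total_row = {col: totals[col] for col in counts.columns if not col.startswith("p_")}
    for x, y in _PAIRS:
        total_row[f"p_{x}_vs_{y}"] = np.nan
    counts.loc["Total"] = pd.Series(total_row)
    for col in [c for c in counts.columns if not c.startswith("p_")]:
        counts[col] = counts[col].astype(int)
    return EvaluationTable(data=counts)


def build_evaluation_table(runs: dict, correctness: dict) -> EvaluationTable:
    """Aggregate per-subject labeling outcomes into the evaluation table.

    ``runs`` maps each of the three method names to a list (one entry per
    subject) of ``{segment: status}`` dicts with statuses
    found/undetected/failed; ``correctness`` maps each method to a parallel
    list of ``{segment: bool}`` dicts judging the found paths (phantom
    ground truth or reviewer labels). A ``failed`` segment (endpoints
    snapped but disconnected) counts as an incorrect path; ``undetected``
    must agree across methods, since all methods share one mask.
    """
    if set(runs) != set(METHODS):
        raise InputError(f"runs must cover exactly the methods {METHODS}, got {sorted(runs)}")
    if set(correctness) != set(METHODS):
        raise InputError(f"correctness must cover exactly the methods {METHODS}")
    n_subjects = {m: len(runs[m]) for m in METHODS}
    if len(set(n_subjects.values())) != 1:
        raise InputError(f"methods ran on different cohort sizes: {n_subjects}")

    rows = {}
    for seg in CANONICAL_SEGMENTS:
        row: dict[str, int] = {"undetected": 0}
        undetected_by_method = {}
        for m in METHODS:
            correct = incorrect = undetected = 0
            for subj_status, subj_correct in zip(runs[m], correctness[m]):
                status = subj_status.get(seg)
                if status is None:
                    raise InputError(f"method {m}: segment {seg} absent from a subject run")
                if status == "undetected":
                    undetected += 1
                elif status == "failed":
                    incorrect += 1
                elif status == "found":
                    if subj_correct.get(seg, False):
                        correct += 1
                    else:
                        incorrect += 1
                else:
                    raise InputError(f"unknown status {status!r} for segment {seg}")
            row[f"{m}_correct"] = correct
            row[f"{m}_incorrect"] = incorrect
            undetected_by_method[m] = undetected
        if len(set(undetected_by_method.values())) != 1:
            raise InputError(
                f"segment {seg}: undetected counts differ across methods "
                f"{undetected_by_method}; all methods share one mask"
            )
        row["undetected"] = undetected_by_method[METHODS[0]]
        rows[seg] = row
    return evaluation_table_from_counts(pd.DataFrame.from_dict(rows, orient="index"))


def time_methods(
    graph,
    skel,
    specs,
    methods: tuple[str, ...] = METHODS,
    repetitions: int = 3,
) -> pd.DataFrame:
    """Wall-clock timing harness for the path-finding stage.

    Reports, per method, the mean and standard deviation of the time to
    label all segments, plus the (shared) skeleton-to-graph construction
    time and its fraction of the total. Timings are hardware-dependent and
    are reported, never asserted against.
    """
    from .labeling import label_segments
    from .skeleton import skeleton_to_graph

    if repetitions < 1:
        raise InputError("repetitions must be >= 1")
    graph_times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        skeleton_to_graph(skel)
        graph_times.append(time.perf_counter() - t0)
    rows = []
    for method in methods:
        times = []
        for _ in range(repetitions):
            t0 = time.perf_counter()
            label_segments(graph, skel, specs, method=method)
            times.append(time.perf_counter() - t0)
        g, p = mean(graph_times), mean(times)
        rows.append(
            {
                "method": method,
                "pathfind_mean_ms": 1e3 * p,
                "pathfind_sd_ms": 1e3 * (stdev(times) if len(times) > 1 else 0.0),
                "graph_mean_ms": 1e3 * g,
                "graph_fraction": g / (g + p) if g + p > 0 else inf,
            }
        )
    return pd.DataFrame(rows).set_index("method")
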