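"""Bundled example data for the documentation worked example.

``example_cohort_counts`` returns per-segment path-finding outcome counts
from a published 60-subject TOF-MRA method-comparison of the same three
algorithms (DFS, Dijkstra, A*) on the 14 circle-of-Willis segments. Each
segment row gives correct/incorrect counts per method plus the number of
subjects in which the vessel was undetected (absent from the binary mask);
the three methods share one mask, so undetected counts are common.

These counts feed :func:`cowlabel.evaluation.evaluation_table_from_counts`
in the README worked example and in the reproduction script.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_cohort_counts", "EXAMPLE_COHORT_SUBJECTS"]

#: Number of subjects in the example cohort.
EXAMPLE_COHORT_SUBJECTS = 60

# segment: (dfs_correct, dfs_incorrect, dijkstra_correct, dijkstra_incorrect,
#           astar_correct, astar_incorrect, undetected)
_COUNTS = {
    "AComm":   (19, 25, 44, 0, 36, 8, 16),
    "R-A1":    (51, 9, 60, 0, 60, 0, 0),
    "L-A1":    (49, 10, 59, 0, 59, 0, 1),
    "R-M1":    (55, 5, 60, 0, 60, 0, 0),
    "L-M1":    (58, 2, 60, 0, 59, 1, 0),
    "R-ICA":   (51, 9, 50, 10, 50, 10, 0),
    "L-ICA":   (51, 9, 52, 8, 52, 8, 0),
    "R-PComm": (8, 6, 14, 0, 14, 0, 46),
    "L-PComm": (10, 8, 18, 0, 18, 0, 42),
    "R-P1":    (52, 8, 57, 3, 58, 2, 0),
    "L-P1":    (51, 9, 60, 0, 60, 0, 0),
    "R-P2":    (55, 5, 60, 0, 60, 0, 0),
    "L-P2":    (51, 9, 60, 0, 60, 0, 0),
    "BA":      (53, 7, 60, 0, 60, 0, 0),
}


def example_cohort_counts() -> pd.DataFrame:
    """Per-segment outcome counts of the example 60-subject cohort."""
    df = pd.DataFrame.from_dict(
        _COUNTS,
        orient="index",
        columns=[
            "dfs_correct",
            "dfs_incorrect",
            "dijkstra_correct",
            "dijkstra_incorrect",
            "astar_correct",
            "astar_incorrect",
            "undetected",
        ],
    )
    df.index.name = "segment"
    return df
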