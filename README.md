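# cowlabel

Semi-automatic labeling of circle-of-Willis (CoW) artery centerlines in 3D
time-of-flight MR angiography (TOF-MRA).

Quantifying intracranial arteries — tortuosity, diameters, segment lengths —
requires each vessel segment's centerline. `cowlabel` implements the
centerline-tracking approach: segment the bright arteries, thin them to a
one-voxel skeleton, convert the skeleton to a weighted graph, and connect a
manually annotated endpoint pair per segment into a named centerline with a
path-finding algorithm. It is aimed at researchers analyzing cerebral MRA
(or similar tubular-structure imaging) who want labeled per-segment
centerlines without training a segmentation network.

## The method

1. **Segmentation.** Otsu's threshold separates bright arteries from
   tissue; 3D seeded region growing from one click in each feeding artery
   (R-ICA, L-ICA, BA) restricts the mask to the arterial tree, and the
   per-seed masks are combined by union. Growing accepts a voxel `v` while
   `|I(v) − μ| ≤ t`, where `μ` is the running mean of accepted voxels.
2. **Skeletonization.** 3D medial-axis thinning reduces the mask to
   one-voxel-wide centerlines.
3. **Graph construction.** Every skeleton voxel is a vertex; every
   26-adjacent voxel pair is an edge with weight `w(u,v) = ‖u − v‖₂` in mm,
   so weights are `{s, s√2, s√3}` at isotropic spacing `s`.
4. **Path finding.** For each of the 14 CoW segments (AComm, R/L-A1,
   R/L-M1, R/L-ICA, R/L-PComm, R/L-P1, R/L-P2, BA), two annotated endpoints
   are snapped to the skeleton and connected by one of:
   * **DFS** — a depth-first maze solver whose backtracking stack is the
     path; valid but not shortest, and prone to detours around the CoW's
     loops;
   * **Dijkstra** — the globally shortest path by `g = Σ w`;
   * **A\*** — best-first on `f = g + h` with `h(v) = ‖v − goal‖₂`;
     admissible, so its cost equals Dijkstra's.
5. **Evaluation.** Per-segment correct/incorrect/undetected counts,
   accuracy `100·c/(c+i)`, and two-sided Fisher's exact tests between
   methods on each segment's 2×2 table.

A segment whose vessel is absent from the mask (hypoplastic or
under-segmented, common for the PComms) is recorded as *undetected* via the
`0 0 0` sentinel in the endpoint file and excluded from accuracy
denominators.

Because real MRA cohorts need downloads and manual annotation, the package
ships a synthetic phantom generator (`cowlabel.phantom`) producing
TOF-MRA-like volumes with CoW loop topology, tortuous ICAs, optional
spurious bridges, ground-truth centerlines, and endpoint files — every
stage is testable offline.

## Worked example

```python
import cowlabel as cl
from cowlabel.datasets import example_cohort_counts

table = cl.evaluation_table_from_counts(example_cohort_counts())
for m in cl.METHODS:
    print(f"{m:9s} accuracy: {table.accuracy(m):.1f}%")
print("AComm DFS accuracy:", table.accuracy("dfs", "AComm"))
print("AComm Dijkstra-vs-A* p:", cl.format_p_value(table.p_value("dijkstra", "astar", "AComm")))
print("AComm undetected:", cl.undetected_percent(16, 60), "%")
```

prints

```
dfs       accuracy: 83.5%
dijkstra  accuracy: 97.1%
astar     accuracy: 96.1%
AComm DFS accuracy: 43.2
AComm Dijkstra-vs-A* p: 0.006
AComm undetected: 26.7 %
```

Over this 60-subject cohort the shortest-path methods clearly beat DFS
(97.1% and 96.1% vs 83.5% of found paths correct), with DFS worst on the
AComm (43.2%) — the segment most often bypassed by a loop detour. The
AComm vessel itself was undetected (absent from the mask) in 26.7% of
subjects.

The full pipeline on a synthetic subject:

```sh
cowlabel phantom --variant complete --seed 1 --out subject/
cowlabel pipeline --in subject/ --method dijkstra
# {"out": "subject/labeled_dijkstra.json", "found": 14, "undetected": 0, "failed": 0}
```

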