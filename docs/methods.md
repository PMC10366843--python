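# Methods

## Pipeline model

The package labels the 14 canonical circle-of-Willis segments (AComm,
R/L-A1, R/L-M1, R/L-ICA, R/L-PComm, R/L-P1, R/L-P2, BA) on a 3D TOF-MRA
volume. The stages and their assumptions:

**Isotropic resampling.** TOF-MRA is typically anisotropic (finer in-plane
than between slices). Volumes are resampled to an isotropic grid with
separable Catmull-Rom cubic convolution (Keys kernel, a = −0.5), which
reproduces linear and quadratic intensity profiles exactly away from the
edges; edge handling is clamping (edge-value replication). The output grid
preserves the physical extent: along a resampled axis,
`n_out = round((n_in − 1)·s_in/s_out) + 1`, sampling at `k·s_out`.
Oblique affines are not honored — only axis-aligned spacing.

**Coordinates.** All modules share 0-based integer voxel indices in
`(x, y, z)` array order. Endpoint annotations are interpreted on the
resampled grid, since annotation happens on the skeleton of the
interpolated data.

**Segmentation.** Otsu's threshold (histogram of 256 bins by default)
estimates the artery/background separation; 3D seeded region growing from
one seed per feeding artery (R-ICA, L-ICA, BA) then keeps only the
connected arterial tree, which suppresses veins and extracranial vessels
without any vesselness model. The growing rule accepts a neighbor `v`
while `|I(v) − μ| ≤ t` with `μ` the running mean of accepted voxels,
updated after every acceptance, visited FIFO with a fixed neighbor order —
this makes the flood deterministic even though the running-mean criterion
is in principle order-dependent. On piecewise-constant intensities the
result coincides with a plain flood fill of `{v : |I(v) − I(seed)| ≤ t}`.

Parameters:

| parameter | default | meaning |
|---|---|---|
| `n_bins` | 256 | Otsu histogram resolution |
| `max_deviation` (`t`) | seed − Otsu, floored at 10% of seed intensity | growing tolerance, intensity units |
| `connectivity` | 6 | face-adjacent growth; 26 optional. 6 limits leakage through thin diagonal gaps |
| `snap_radius` | 3 voxels | max distance from an annotated endpoint to the skeleton |

The tolerance default ties the two preprocessing steps together: a seed at
intensity `I₀` grows as long as intensities stay within `I₀ − t =` Otsu
threshold, so the flood stops near the class boundary. Under-segmentation
is legal output — a missing vessel surfaces downstream as "undetected",
not as an error.

**Skeletonization.** 3D medial-axis thinning (Lee-style, as implemented in
scikit-image) is treated as a black box behind two contracts the rest of
the pipeline actually needs: the skeleton is a subset of the mask, and the
number of 26-connected components is preserved. Both are asserted in
tests; the algorithm identity is not.

**Graph.** Dense per-voxel graph: every skeleton voxel is a node, every
26-adjacent pair an edge weighted by the Euclidean distance between the
voxel centers in mm. Dense (rather than a junction/branch summary) because
path reconstruction needs the full voxel chain; 26-connectivity because
1-voxel-wide diagonal skeleton runs are only connected diagonally, and it
yields the `{s, s√2, s√3}` weight set at isotropic spacing `s`.

**Path finding.** Three methods, all deterministic:

* *DFS maze solver*: push visited voxels on a stack, backtrack at dead
  ends; the stack at goal arrival is the path. Neighbor visiting order is
  lexicographic over the `(dz, dy, dx)` offset. The path is simple and
  valid but has no optimality guarantee — on looped anatomy (the CoW ring)
  the fixed order can commit to the long way around before finding the
  goal.
* *Dijkstra*: binary-heap implementation with `(distance, node)` heap
  entries, so priority ties pop the lexicographically smallest coordinate.
  Strict-improvement predecessor updates give one deterministic shortest
  path among equals.
* *A\**: same structure on `f = g + h` with `h(v)` the straight-line mm
  distance to the goal. Edge weights are themselves Euclidean lengths, so
  `h` is consistent (triangle inequality) and A\* returns the Dijkstra
  cost.

`start == goal` returns a zero-length single-node path rather than an
error: adjacent segments share branch points (ICA terminus, basilar tip),
so coincident queries are plausible. A brute-force exhaustive enumeration
of simple paths (with a cost-bound prune and a refusal guard at 10⁶
extensions) ships in the package as the test oracle; it is never used in
the pipeline.

**Labeling.** Per segment: sentinel annotations pass through as
*undetected*; endpoints that cannot be snapped within `snap_radius` are
also *undetected* (a missing vessel and a failed snap are observationally
the same event — nothing to track); two snapped endpoints in different
skeleton components are *failed* (a broken skeleton, worth distinguishing).
Failures are recorded per segment, never raised.

**Evaluation.** Accuracy is `100·correct/(correct+incorrect)` over found
paths, reported to one decimal (half-up). Undetected segments are excluded
from the denominator. Method pairs are compared per segment with a
two-sided Fisher's exact test under the minimum-likelihood convention: sum
hypergeometric point probabilities (margins fixed) of every table no more
probable than the observed one, with 1e-7 relative slack when comparing
point probabilities to absorb floating-point noise. Point probabilities
use log-factorials (`lgamma`), stable at cohort sizes in the hundreds.
p-values render as `<0.001` below 0.0005 and `1` at the top, matching
standard table formatting. When building the table from per-subject runs,
a *failed* path counts as incorrect (it is a path-finding failure on an
existing vessel), and undetected counts must agree across methods since
all methods share one mask. Correctness judgments are an explicit input —
ground-truth distance on phantoms (mean distance < 1 voxel to the true
centerline), reviewer labels on real data — never computed from real
images.

The timing harness (`time_methods`) reports mean ± sd wall-clock per
method and the skeleton-to-graph construction time separately (graph
construction dominates in practice); timings are hardware-dependent and
are reported, never asserted.

## The phantom generator

`cowlabel.phantom` emulates what the algorithms consume, not MRA physics:
bright tubes (default intensity 300) on a dark background (50) with
additive Gaussian noise (default sd 10, i.e. vessel SNR 30 — comfortably
inside the regime where Otsu separates the classes, enforced as
`intensity > background + 5·sd`), on a 128³ grid at 0.6 mm isotropic
spacing with tube radius 2 voxels. Geometry is schematic: the CoW ring
lies in one axial plane, the ICAs rise through an S-shaped "siphon", and
the BA rises straight. Topology is what matters: ICA→A1+M1 bifurcations,
BA→P1+P1, AComm closing the anterior loop, PComms closing the posterior
loops. Variants:

* `complete` — all 14 segments; the ring is closed.
* `looped` — same wiring, named for the failure substrate: any anterior
  query can detour the long way around the communicating ring. The DFS
  AComm path comes out several times longer than the Dijkstra path.
* `missing_pcomms` — both PComms omitted (the common hypoplastic variant);
  their endpoint lines carry the `0 0 0` sentinel.
* `bridged` — a spurious radius-1.5 tube connects two ICA siphon bends, so
  the globally shortest ICA path undercuts the true route (ratio ≈ 0.82)
  while DFS can keep the anatomically correct detour.

Ground truth per vessel: the dense-sampled centerline rounded to voxels
(26-connected by construction), the analytic polyline length in mm, and
the exact rasterized tube mask (voxels within the radius of the
piecewise-linear curve, by point-to-segment distance). Everything is
deterministic from the seed; the manifest written by `write_phantom`
suffices to regenerate the volume bit for bit.

What the phantom does **not** model — and hence what passing tests do not
show about real data: flow-related enhancement and inflow saturation,
partial-volume intensity gradients at vessel walls, vessel caliber
variation, anatomical variability of the CoW beyond presence/absence of
the PComms, and skeletonization artifacts other than the explicit bridge.
Real-data accuracy claims require real cohorts and human correctness
review.

## Numerical choices

* Edge weights and path lengths in mm; the A* heuristic uses the same
  units (mixing voxel-unit `h` with mm `g` would break admissibility at
  anisotropic spacing).
* Path validity (endpoints, simplicity, 26-adjacency, length = Σ weights
  to 1e-9) is checked by a shared validator on every labeled path, not
  trusted from the algorithms.
* Snap ties (equidistant skeleton voxels) break lexicographically by
  coordinate.
* Otsu on a constant volume, accuracy with an empty denominator, and
  non-positive spacing are errors, not NaNs.
* Reported percentages round half-up to one decimal; Fisher p-values to
  three.

## Problem sizes

Tests and the reproduction script run entirely on desk-scale inputs: 128³
phantoms (pipeline ≈ 1 s per variant), random graphs of ≤ 12 nodes for the
200-trial oracle comparison, and Fisher tables with totals up to 200 for
the enumeration cross-check. These sizes were chosen so the whole suite
exercises every contract in seconds while remaining exhaustive where
exhaustiveness is the point (brute-force path enumeration, full
hypergeometric support sums).

## Known limitations

* Only axis-aligned spacing is honored when resampling; oblique NIfTI
  affines are ignored.
* The region-growing tolerance default is a heuristic link between Otsu
  and the seed intensity; real cohorts may need per-subject tuning.
* DFS path shape depends on the fixed neighbor order; other orders produce
  other (equally valid, equally non-shortest) paths, so only qualitative
  detour behavior is contractual.
* A2/M2 and more distal segments are out of scope, as are automatic seed
  or landmark detection and deep-learning segmentation.
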