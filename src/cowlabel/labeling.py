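"""Run a path-finding method over all 14 annotated segments; export results.

Per-segment outcomes:

* ``found`` — both endpoints snapped to the skeleton and a path connects them;
* ``undetected`` — the annotation carried the ``0 0 0`` sentinel (vessel
  absent from the mask, e.g. a hypoplastic PComm), or an endpoint could not
  be snapped to any nearby skeleton voxel;
* ``failed`` — both endpoints snapped but lie in different skeleton
  components, so no path exists. This is kept distinct from ``undetected``
  because it points at a broken skeleton rather than a missing vessel.

Failures are recorded per segment, never raised, so one bad segment cannot
abort a subject.
"""

from __future__ import annotations

import base64
import csv
import io
import json
from dataclasses import dataclass
from pathlib import Path as FsPath

from .errors import InputError, NoPathError, SnapError
from .pathfinding import Path, find_path, validate_path
from .segmentation import BinaryMask
from .skeleton import SkeletonGraph, snap_to_skeleton
from .volume_io import CANONICAL_SEGMENTS, VesselSegmentSpec

__all__ = [
    "SegmentResult",
    "LabeledCenterlines",
    "label_segments",
    "export_labeled_centerlines",
    "read_labeled_csv",
    "SEGMENT_PALETTE",
]

#: Fixed display colors keyed by canonical segment name (hex RGB).
SEGMENT_PALETTE: dict[str, str] = {
    "AComm": "#e6194b",
    "R-A1": "#3cb44b",
    "L-A1": "#ffe119",
    "R-M1": "#4363d8",
    "L-M1": "#f58231",
    "R-ICA": "#911eb4",
    "L-ICA": "#46f0f0",
    "R-PComm": "#f032e6",
    "L-PComm": "#bcf60c",
    "R-P1": "#fabebe",
    "L-P1": "#008080",
    "R-P2": "#e6beff",
    "L-P2": "#9a6324",
    "BA": "#800000",
}


@dataclass(frozen=True)
class SegmentResult:
    """Outcome for one vessel segment."""

    name: str
    status: str  # found | undetected | failed
    path: Path | None = None
    length_mm: float | None = None
    detail: str = ""


@dataclass(frozen=True)
class LabeledCenterlines:
    """One record per canonical segment, in canonical order."""

    records: tuple[SegmentResult, ...]

    def __post_init__(self):
        names = tuple(r.name for r in self.records)
        if names != CANONICAL_SEGMENTS:
            raise InputError("records must cover the 14 canonical segments in order")

    def __getitem__(self, name: str) -> SegmentResult:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def counts(self) -> dict[str, int]:
        out = {"found": 0, "undetected": 0, "failed": 0}
        for r in self.records:
            out[r.status] += 1
        return out


def label_segments(
    graph: SkeletonGraph,
    skel: BinaryMask,
    specs: list[VesselSegmentSpec],
    method: str = "dijkstra",
    snap_radius: float = 3.0,
) -> LabeledCenterlines:
    """Label all 14 segments by snapping endpoints and running ``method``.

    ``skel`` is the skeleton mask the graph was built from; it provides the
    voxel set for endpoint snapping. Sentinel specs pass through as
    undetected. Shared endpoints between segments (branch points like the
    ICA terminus) are legal and simply produce overlapping path termini.
    """
    by_name = {s.name: s for s in specs}
    absent = [n for n in CANONICAL_SEGMENTS if n not in by_name]
    if absent:
        raise InputError(f"specs must cover all 14 segments; missing {absent}")
    records = []
    for name in CANONICAL_SEGMENTS:
        spec = by_name[name]
        if spec.missing:
            records.append(SegmentResult(name=name, status="undetected", detail="sentinel"))
            continue
        try:
            a = snap_to_skeleton(spec.endpoint_a, skel, max_radius=snap_radius)
            b = snap_to_skeleton(spec.endpoint_b, skel, max_radius=snap_radius)
        except SnapError as exc:
            records.append(SegmentResult(name=name, status="undetected", detail=str(exc)))
            continue
        try:
            path = find_path(graph, a, b, method)
        except NoPathError as exc:
            records.append(SegmentResult(name=name, status="failed", detail=str(exc)))
            continue
        validate_path(path, graph, a, b)
        records.append(
            SegmentResult(name=name, status="found", path=path, length_mm=path.length_mm)
        )
    return LabeledCenterlines(records=tuple(records))


def export_labeled_centerlines(
    result: LabeledCenterlines,
    path: str | FsPath,
    format: str = "csv",
) -> None:
    """Write labeled centerlines as CSV, JSON, or a static HTML 3D view.

    CSV/JSON list one row per path voxel (segment, order index, x, y, z);
    segments without a path contribute a status row with empty coordinates.
    HTML embeds the same traces as JSON plus a static 3D render.
    """
    path = FsPath(path)
    if format == "csv":
        _write_csv(result, path)
    elif format == "json":
        _write_json(result, path)
    elif format == "html":
        _write_html(result, path)
    else:
        raise InputError(f"unknown export format {format!r}")


def _write_csv(result: LabeledCenterlines, path: FsPath) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment", "status", "order", "x", "y", "z"])
        for rec in result.records:
            if rec.status == "found" and rec.path is not None:
                for i, (x, y, z) in enumerate(rec.path.voxels):
                    writer.writerow([rec.name, rec.status, i, x, y, z])
            else:
                writer.writerow([rec.name, rec.status, "", "", "", ""])


def read_labeled_csv(path: str | FsPath) -> dict[str, dict]:
    """Re-read a CSV export: segment -> {status, voxels}."""
    out: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rec = out.setdefault(row["segment"], {"status": row["status"], "voxels": []})
            if row["order"] != "":
                rec["voxels"].append((int(row["x"]), int(row["y"]), int(row["z"])))
    return out


def _as_traces(result: LabeledCenterlines) -> list[dict]:
    traces = []
    for rec in result.records:
        entry: dict = {"name": rec.name, "status": rec.status, "color": SEGMENT_PALETTE[rec.name]}
        if rec.status == "found" and rec.path is not None:
            entry["length_mm"] = rec.length_mm
            entry["voxels"] = [list(v) for v in rec.path.voxels]
        traces.append(entry)
    return traces


def _write_json(result: LabeledCenterlines, path: FsPath) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"segments": _as_traces(result)}, fh, indent=1)


def _render_png_base64(result: LabeledCenterlines) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="3d")
    for rec in result.records:
        if rec.status != "found" or rec.path is None:
            continue
        xs, ys, zs = zip(*rec.path.voxels)
        ax.plot(xs, ys, zs, color=SEGMENT_PALETTE[rec.name], label=rec.name, linewidth=2)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    if any(r.status == "found" for r in result.records):
        ax.legend(fontsize=6, loc="upper left", ncol=2)
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _write_html(result: LabeledCenterlines, path: FsPath) -> None:
    traces = _as_traces(result)
    png = _render_png_base64(result)
    rows = "\n".join(
        f'<tr><td style="color:{t["color"]}">&#9632;</td><td>{t["name"]}</td>'
        f'<td>{t["status"]}</td>'
        f'<td>{t.get("length_mm", float("nan")):.2f}</td></tr>'
        if "length_mm" in t
        else f'<tr><td style="color:{t["color"]}">&#9632;</td><td>{t["name"]}</td>'
        f'<td>{t["status"]}</td><td>-</td></tr>'
        for t in traces
    )
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Labeled centerlines</title></head>
<body>
<h1>Labeled circle-of-Willis centerlines</h1>
<img alt="3D centerline render" src="data:image/png;base64,{png}"/>
<table border="1"><tr><th></th><th>segment</th><th>status</th><th>length (mm)</th></tr>
{rows}
</table>
<script type="application/json" id="centerline-traces">
{json.dumps({"segments": traces})}
</script>
</body></html>
"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(html)
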