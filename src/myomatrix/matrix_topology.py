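"""Longitudinal segment graph, junction events, tracking, branching statistics.

The segment graph treats every label of a reoriented :class:`LabeledVolume`
as one node spanning its occupied slice range (short longitudinal gaps, e.g.
SRT planes, are bridged). Two labels are linked when one ends and the other
begins within ``max_gap`` slices with cross-sectional footprints overlapping
by at least ``min_overlap_voxels``. Connected components of these links are
junction events: one parent with several children is a split, several
parents with one child a merge; an event is "single" when the larger side
has exactly two segments and "multi" otherwise, and contributes
``max(|parents|, |children|) - 1`` branches.

Myofibril tracking seeds one track per label present in the first analysis
slice and walks the graph downstream; at a split it follows the child whose
mean sarcolemma distance is closest to the seed's (ties to the smaller
label), and it continues straight through merges. Tracks that leave the
lateral field of view, or whose path terminates before the last slice, are
censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabeledVolume, MaskVolume, VolumeError

__all__ = [
    "SegmentNode",
    "JunctionEvent",
    "SegmentGraph",
    "MyofibrilTrack",
    "build_segment_graph",
    "count_sarcomeres",
    "track_myofibrils",
    "branching_statistics",
    "event_boundary_distances",
    "sarcomere_boundary_distances",
]


class TopologyError(VolumeError):
    pass


@dataclass
class SegmentNode:
    label: int
    z_start: int  # half-open [z_start, z_end)
    z_end: int
    voxel_count: int
    centroids: dict  # z -> (row, col) over occupied slices
    touches_lateral: bool
    mean_boundary_distance: float | None = None
    sarcomere_count: int | None = None


@dataclass(frozen=True)
class JunctionEvent:
    z_position: int
    type: str  # split | merge
    classification: str  # single | multi
    parent_labels: tuple[int, ...]
    child_labels: tuple[int, ...]
    branch_count: int


@dataclass
class SegmentGraph:
    nodes: dict[int, SegmentNode]
    events: list[JunctionEvent]
    continuations: list[tuple[int, int]]
    censored_labels: set[int]
    z_first: int
    z_last: int
    labels: LabeledVolume

    def events_of_parent(self, label: int) -> "JunctionEvent | None":
        return self._by_parent.get(label)

    def __post_init__(self):
        self._by_parent = {}
        for ev in self.events:
            for p in ev.parent_labels:
                self._by_parent[p] = ev
        self._continuation_of = dict(self.continuations)

    def continuation_of(self, label: int) -> int | None:
        return self._continuation_of.get(label)


@dataclass
class MyofibrilTrack:
    seed_label: int
    path: list[int]
    events_encountered: list[JunctionEvent]
    sarcomeres_traversed: int  # observable sarcomeres (downstream boundary in view)
    branching_sarcomere_count: int
    n_single: int
    n_multi: int
    total_branch_count: int
    censored: bool


def build_segment_graph(
    labels: LabeledVolume, min_overlap_voxels: int = 1, max_gap: int = 5
) -> SegmentGraph:
    """Build the directed longitudinal segment graph of a labeled volume."""
    data = labels.data
    if data.max() == 0:
        raise TopologyError("labels volume is empty")
    n_long, n_row, n_col = data.shape

    slices_of: dict[int, list[int]] = {}
    counts: dict[int, int] = {}
    centroids: dict[int, dict] = {}
    occupied = []
    for z in range(n_long):
        flat = data[z].ravel()
        nz = np.flatnonzero(flat)
        if nz.size == 0:
            continue
        occupied.append(z)
        labs = flat[nz]
        uniq = np.unique(labs)
        cnt = np.bincount(labs)
        rsum = np.bincount(labs, weights=nz // n_col)
        csum = np.bincount(labs, weights=nz % n_col)
        for lab in uniq:
            lab = int(lab)
            slices_of.setdefault(lab, []).append(z)
            counts[lab] = counts.get(lab, 0) + int(cnt[lab])
            centroids.setdefault(lab, {})[z] = (
                rsum[lab] / cnt[lab], csum[lab] / cnt[lab]
            )
    z_first, z_last = occupied[0], occupied[-1]

    lateral = set()
    for face in (data[:, 0, :], data[:, -1, :], data[:, :, 0], data[:, :, -1]):
        lateral.update(int(l) for l in np.unique(face) if l > 0)

    nodes = {}
    for lab, zs in slices_of.items():
        zs = np.asarray(zs)
        gaps = np.diff(zs) - 1
        if gaps.size and gaps.max() > max_gap:
            raise TopologyError(
                f"label {lab} re-appears after a gap of {int(gaps.max())} slices "
                f"(> max_gap={max_gap}); labels must not be reused"
            )
        nodes[lab] = SegmentNode(
            lab, int(zs[0]), int(zs[-1]) + 1, counts[lab], centroids[lab],
            lab in lateral,
        )

    starters_at: dict[int, list[int]] = {}
    for lab, node in nodes.items():
        starters_at.setdefault(node.z_start, []).append(lab)

    def footprint(lab: int, z: int) -> np.ndarray:
        return np.flatnonzero(data[z].ravel() == lab)

    edges = []
    for lab, node in nodes.items():
        t = node.z_end - 1
        fp = None
        for z in range(t + 1, min(t + 1 + max_gap, n_long - 1) + 1):
            for cand in starters_at.get(z, ()):  # labels starting at z
                if cand == lab:
                    continue
                if fp is None:
                    fp = footprint(lab, t)
                ov = np.intersect1d(fp, footprint(cand, z), assume_unique=True).size
                if ov >= min_overlap_voxels:
                    edges.append((lab, cand))

    # connected components of the link relation are junction events
    comp = {}
    for a, b in edges:
        comp.setdefault(("p", a), ("p", a))
        comp.setdefault(("c", b), ("c", b))

    def cfind(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x
    for a, b in edges:
        ra, rb = cfind(("p", a)), cfind(("c", b))
        if ra != rb:
            comp[ra] = rb
    groups: dict = {}
    for a, b in edges:
        groups.setdefault(cfind(("p", a)), [set(), set()])
        root = cfind(("p", a))
        groups[root][0].add(a)
        groups[root][1].add(b)

    events, continuations = [], []
    for parents, children in groups.values():
        p, c = len(parents), len(children)
        z_pos = min(nodes[ch].z_start for ch in children)
        if p == 1 and c == 1:
            continuations.append((next(iter(parents)), next(iter(children))))
            continue
        etype = "split" if c >= p else "merge"
        branch_count = max(p, c) - 1
        classification = "single" if max(p, c) == 2 else "multi"
        events.append(JunctionEvent(
            z_pos, etype, classification,
            tuple(sorted(parents)), tuple(sorted(children)), branch_count,
        ))
    events.sort(key=lambda e: (e.z_position, e.parent_labels))

    return SegmentGraph(nodes, events, continuations, lateral, z_first, z_last, labels)


def count_sarcomeres(
    node: SegmentNode,
    srt: MaskVolume | None = None,
    nominal_sarcomere_length: float | None = None,
    voxel_size_z: float | None = None,
) -> int:
    """Sarcomeres spanned by a segment.

    With an SRT mask: one plus the number of internal SRT-plane crossings of
    the segment's centroid track. Without: the segment length divided by the
    nominal sarcomere length, rounded, at least 1.
    """
    if srt is None and nominal_sarcomere_length is None:
        raise TopologyError("count_sarcomeres needs an SRT mask or a nominal length")
    if srt is not None:
        data = srt.data
        last_rc = None
        prev_in_srt = False
        crossings = 0
        for z in range(node.z_start, node.z_end):
            rc = node.centroids.get(z, last_rc)
            last_rc = rc
            r, c = int(round(rc[0])), int(round(rc[1]))
            in_srt = bool(data[z, r, c])
            if in_srt and not prev_in_srt and z > node.z_start:
                crossings += 1
            prev_in_srt = in_srt
        node.sarcomere_count = crossings + 1
        return node.sarcomere_count
    dz = voxel_size_z if voxel_size_z is not None else 1.0
    length_nm = (node.z_end - node.z_start) * dz
    node.sarcomere_count = max(1, round(length_nm / nominal_sarcomere_length))
    return node.sarcomere_count


def _node_mean_distances(graph: SegmentGraph, boundary_distance: np.ndarray) -> None:
    data = graph.labels.data
    flat = data.ravel()
    sums = np.bincount(flat, weights=boundary_distance.ravel())
    cnts = np.bincount(flat)
    for lab, node in graph.nodes.items():
        node.mean_boundary_distance = float(sums[lab] / cnts[lab])


def track_myofibrils(
    graph: SegmentGraph,
    boundary_distance: np.ndarray,
    srt: MaskVolume | None = None,
    nominal_sarcomere_length: float | None = None,
) -> list[MyofibrilTrack]:
    """Track every first-slice myofibril downstream through the graph.

    ``boundary_distance`` is the sarcolemma distance volume (nm) aligned
    with the graph's label volume. A track's ``sarcomeres_traversed`` counts
    observable sarcomeres: those whose downstream boundary lies inside the
    field of view (the path's physical sarcomere count minus one).
    """
    if boundary_distance is None:
        raise TopologyError("tracking requires a boundary distance map")
    if boundary_distance.shape != graph.labels.data.shape:
        raise TopologyError("distance map shape differs from labels volume")
    _node_mean_distances(graph, boundary_distance)
    dz = graph.labels.grid.voxel_size[0]

    tracks = []
    seeds = sorted(
        lab for lab, n in graph.nodes.items() if n.z_start == graph.z_first
    )
    for seed in seeds:
        d_seed = graph.nodes[seed].mean_boundary_distance
        path = [seed]
        events = []
        current = seed
        while True:
            ev = graph.events_of_parent(current)
            if ev is None:
                nxt = graph.continuation_of(current)
                if nxt is None:
                    break
                path.append(nxt)
                current = nxt
                continue
            events.append(ev)
            if ev.type == "merge":
                nxt = ev.child_labels[0]
            else:
                nxt = min(
                    ev.child_labels,
                    key=lambda ch: (
                        abs(graph.nodes[ch].mean_boundary_distance - d_seed), ch
                    ),
                )
            path.append(nxt)
            current = nxt
        physical = sum(
            count_sarcomeres(graph.nodes[lab], srt, nominal_sarcomere_length, dz)
            for lab in path
        )
        observable = max(0, physical - 1)
        censored = any(graph.nodes[lab].touches_lateral for lab in path) or (
            graph.nodes[path[-1]].z_end - 1 < graph.z_last
        )
        n_single = sum(1 for e in events if e.classification == "single")
        n_multi = len(events) - n_single
        tracks.append(MyofibrilTrack(
            seed, path, events,
            observable,
            min(len(events), observable),
            n_single, n_multi,
            sum(e.branch_count for e in events),
            censored,
        ))
    return tracks


def branching_statistics(tracks: list[MyofibrilTrack]) -> dict[str, float]:
    """Per-cell branching metrics over a set of myofibril tracks.

    Percent-of-myofibril and per-track metrics use complete (uncensored)
    tracks only; pooled per-sarcomere metrics retain the pre-exit sarcomeres
    of censored tracks. Splits and merges both count as branching.
    """
    complete = [t for t in tracks if not t.censored]
    if not complete:
        raise TopologyError("no uncensored tracks; cannot compute statistics")
    n_branched = sum(1 for t in complete if t.events_encountered)
    per_track_pct = [
        100.0 * t.branching_sarcomere_count / t.sarcomeres_traversed
        for t in complete if t.sarcomeres_traversed > 0
    ]
    pool = [t for t in tracks if t.sarcomeres_traversed > 0]
    total_sarc = sum(t.sarcomeres_traversed for t in pool)
    total_branching = sum(t.branching_sarcomere_count for t in pool)
    total_branches = sum(t.total_branch_count for t in pool)
    total_single = sum(t.n_single for t in pool)
    total_multi = sum(t.n_multi for t in pool)
    return {
        "n_tracks": len(tracks),
        "n_complete_tracks": len(complete),
        "n_censored_tracks": len(tracks) - len(complete),
        "pct_myofibrils_branched": 100.0 * n_branched / len(complete),
        "pct_sarcomeres_branched_mean": float(np.mean(per_track_pct)),
        "pct_sarcomeres_branched": 100.0 * total_branching / total_sarc,
        "pct_single": 100.0 * total_single / total_sarc,
        "pct_multi": 100.0 * total_multi / total_sarc,
        "branches_per_10": 10.0 * total_branches / total_sarc,
        "total_sarcomeres": total_sarc,
    }


def event_boundary_distances(
    tracks: list[MyofibrilTrack], graph: SegmentGraph, boundary_distance: np.ndarray
) -> np.ndarray:
    """Sarcolemma distance (nm) at each distinct event encountered by tracks."""
    seen, out = set(), []
    for t in tracks:
        for ev in t.events_encountered:
            key = (ev.z_position, ev.parent_labels)
            if key in seen:
                continue
            seen.add(key)
            parent = graph.nodes[ev.parent_labels[0]]
            z = parent.z_end - 1
            r, c = parent.centroids[max(k for k in parent.centroids if k <= z)]
            out.append(boundary_distance[z, int(round(r)), int(round(c))])
    return np.asarray(out, dtype=float)


def sarcomere_boundary_distances(
    tracks: list[MyofibrilTrack], graph: SegmentGraph, boundary_distance: np.ndarray,
    boundary_positions: "list[int] | np.ndarray",
) -> np.ndarray:
    """Sarcolemma distance at every track position at each sarcomere boundary.

    ``boundary_positions`` are the slice indices of sarcomere boundaries
    (e.g. SRT plane starts); together these form the reference distribution
    for the peripheral-bias test.
    """
    out = []
    for t in tracks:
        if t.censored:
            continue
        for z in boundary_positions:
            node = next(
                (graph.nodes[l] for l in t.path
                 if graph.nodes[l].z_start <= z < graph.nodes[l].z_end), None
            )
            if node is None:
                continue
            zs = [k for k in node.centroids if k <= z]
            r, c = node.centroids[max(zs)] if zs else node.centroids[min(node.centroids)]
            out.append(boundary_distance[z, int(round(r)), int(round(c))])
    return np.asarray(out, dtype=float)
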