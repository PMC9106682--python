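import numpy as np
import pytest

from myomatrix.matrix_topology import (
    JunctionEvent,
    MyofibrilTrack,
    TopologyError,
    branching_statistics,
    build_segment_graph,
    count_sarcomeres,
    event_boundary_distances,
    track_myofibrils,
)
from myomatrix.morphometry_spatial import boundary_distance_map
from myomatrix.synthetic_muscle import generate_muscle_volume
from myomatrix.volume_io import LabeledVolume, MaskVolume, VoxelGrid

from conftest import small_config


def volume(data, voxel=(20.0, 20.0, 20.0)):
    return LabeledVolume(VoxelGrid(data.shape, voxel), np.asarray(data, dtype=np.int32))


def square(data, z0, z1, r0, r1, c0, c1, label):
    data[z0:z1, r0:r1, c0:c1] = label


class TestBuildSegmentGraph:
    def test_straight_cylinder_one_node_no_events(self):
        data = np.zeros((20, 10, 10), dtype=np.int32)
        square(data, 0, 20, 3, 7, 3, 7, 1)
        g = build_segment_graph(volume(data))
        assert len(g.nodes) == 1 and g.events == []
        node = g.nodes[1]
        assert (node.z_start, node.z_end) == (0, 20)
        assert node.voxel_count == 20 * 16

    def test_hand_coded_y_split(self):
        # label 1 for z<10 spanning cols 2..8; labels 2 and 3 for z>=10,
        # both overlapping label 1's terminal footprint
        data = np.zeros((20, 12, 12), dtype=np.int32)
        square(data, 0, 10, 4, 8, 2, 8, 1)
        square(data, 10, 20, 4, 8, 2, 4, 2)
        square(data, 10, 20, 4, 8, 6, 8, 3)
        g = build_segment_graph(volume(data))
        # brute-force oracle on the coded array: footprint intersections
        f1 = set(map(tuple, np.argwhere(data[9] == 1)))
        f2 = set(map(tuple, np.argwhere(data[10] == 2)))
        f3 = set(map(tuple, np.argwhere(data[10] == 3)))
        assert f1 & f2 and f1 & f3 and not f2 & f3
        assert len(g.events) == 1
        ev = g.events[0]
        assert ev.type == "split"
        assert ev.classification == "single"
        assert ev.parent_labels == (1,) and ev.child_labels == (2, 3)
        assert ev.branch_count == 1
        assert ev.z_position == 10

    def test_one_to_three_multi_split(self):
        data = np.zeros((20, 12, 18), dtype=np.int32)
        square(data, 0, 10, 4, 8, 2, 14, 1)
        square(data, 10, 20, 4, 8, 2, 5, 2)
        square(data, 10, 20, 4, 8, 7, 10, 3)
        square(data, 10, 20, 4, 8, 11, 14, 4)
        g = build_segment_graph(volume(data))
        ev, = g.events
        assert ev.type == "split" and ev.classification == "multi"
        assert ev.branch_count == 2

    def test_merge_is_split_reversed(self):
        data = np.zeros((20, 12, 12), dtype=np.int32)
        square(data, 0, 10, 4, 8, 2, 4, 1)
        square(data, 0, 10, 4, 8, 6, 8, 2)
        square(data, 10, 20, 4, 8, 2, 8, 3)
        g = build_segment_graph(volume(data))
        ev, = g.events
        assert ev.type == "merge"
        assert ev.parent_labels == (1, 2) and ev.child_labels == (3,)
        assert ev.branch_count == 1

    def test_bridges_gap_up_to_max_gap(self):
        data = np.zeros((21, 8, 8), dtype=np.int32)
        square(data, 0, 9, 2, 6, 2, 6, 1)
        square(data, 12, 21, 2, 6, 2, 6, 2)  # 3-slice gap
        g = build_segment_graph(volume(data), max_gap=3)
        assert g.continuations == [(1, 2)]
        g2 = build_segment_graph(volume(data), max_gap=2)
        assert g2.continuations == [] and g2.events == []

    def test_min_overlap_threshold(self):
        data = np.zeros((10, 8, 8), dtype=np.int32)
        square(data, 0, 5, 2, 6, 2, 6, 1)
        square(data, 5, 10, 2, 6, 5, 7, 2)  # 4-voxel-wide overlap per row
        assert build_segment_graph(volume(data), min_overlap_voxels=10).events == []
        assert len(build_segment_graph(volume(data), min_overlap_voxels=2).continuations) == 1

    def test_empty_volume_rejected(self):
        with pytest.raises(TopologyError):
            build_segment_graph(volume(np.zeros((4, 4, 4))))

    def test_label_reuse_rejected(self):
        data = np.zeros((30, 8, 8), dtype=np.int32)
        square(data, 0, 5, 2, 6, 2, 6, 1)
        square(data, 20, 30, 2, 6, 2, 6, 1)  # same label after a 15-slice gap
        with pytest.raises(TopologyError, match="re-appears"):
            build_segment_graph(volume(data), max_gap=5)

    def test_lateral_touching_labels_flagged(self):
        data = np.zeros((10, 8, 8), dtype=np.int32)
        square(data, 0, 10, 0, 4, 2, 6, 1)  # touches row 0 face
        square(data, 0, 10, 5, 7, 2, 6, 2)
        g = build_segment_graph(volume(data))
        assert g.censored_labels == {1}


class TestCountSarcomeres:
    def _node(self, data, label=1):
        return build_segment_graph(volume(data)).nodes[label]

    def test_no_crossings_one_sarcomere(self):
        data = np.zeros((10, 8, 8), dtype=np.int32)
        square(data, 0, 10, 2, 6, 2, 6, 1)
        srt = MaskVolume(VoxelGrid(data.shape, (20, 20, 20)), np.zeros_like(data, np.uint8), "SRT")
        assert count_sarcomeres(self._node(data), srt=srt) == 1

    def test_four_crossings_five_sarcomeres(self):
        data = np.zeros((52, 8, 8), dtype=np.int32)
        srt_data = np.zeros_like(data, dtype=np.uint8)
        for k in range(5):  # 10-slice sarcomeres separated by 1-voxel planes
            square(data, k * 10 + (k > 0), k * 10 + 10, 2, 6, 2, 6, 1)
        for z in (10, 20, 30, 40):
            srt_data[z] = 1
            data[z] = 0
        srt = MaskVolume(VoxelGrid(data.shape, (20, 20, 20)), srt_data, "SRT")
        node = build_segment_graph(volume(data), max_gap=2).nodes[1]
        assert count_sarcomeres(node, srt=srt) == 5

    def test_nominal_length_fallback(self):
        data = np.zeros((100, 8, 8), dtype=np.int32)
        square(data, 0, 100, 2, 6, 2, 6, 1)
        node = self._node(data)
        # 100 slices * 320 nm = 32 um at nominal 3.2 um -> 10
        assert count_sarcomeres(node, nominal_sarcomere_length=3200.0, voxel_size_z=320.0) == 10

    def test_requires_some_input(self):
        data = np.zeros((5, 8, 8), dtype=np.int32)
        square(data, 0, 5, 2, 6, 2, 6, 1)
        with pytest.raises(TopologyError):
            count_sarcomeres(self._node(data))


class TestTracking:
    def test_no_events_pass_through(self):
        data = np.zeros((20, 16, 16), dtype=np.int32)
        square(data, 0, 20, 2, 6, 2, 6, 1)
        square(data, 0, 20, 9, 13, 9, 13, 2)
        vol = volume(data)
        cell = MaskVolume(vol.grid, np.ones_like(data, np.uint8), "cell")
        cell.data[:, 0, :] = 0
        dist = boundary_distance_map(cell)
        g = build_segment_graph(vol)
        tracks = track_myofibrils(g, dist, nominal_sarcomere_length=80.0)
        assert [t.seed_label for t in tracks] == [1, 2]
        assert all(not t.censored and t.events_encountered == [] for t in tracks)

    def test_split_follows_closest_boundary_distance(self):
        # seed near row 6; children at rows ~5 (close) and ~12 (far)
        data = np.zeros((20, 16, 16), dtype=np.int32)
        square(data, 0, 10, 4, 8, 4, 12, 1)
        square(data, 10, 20, 4, 7, 4, 12, 2)  # stays near seed depth
        square(data, 10, 20, 7, 14, 4, 12, 3)  # moves toward the interior
        vol = volume(data)
        cell = MaskVolume(vol.grid, np.ones_like(data, np.uint8), "cell")
        cell.data[:, 0, :] = 0  # boundary at row 0 only
        dist = boundary_distance_map(cell)
        g = build_segment_graph(vol)
        tracks = track_myofibrils(g, dist, nominal_sarcomere_length=200.0)
        t = tracks[0]
        assert t.path == [1, 2]
        assert len(t.events_encountered) == 1

    def test_track_through_merge(self):
        data = np.zeros((20, 12, 12), dtype=np.int32)
        square(data, 0, 10, 4, 8, 2, 4, 1)
        square(data, 0, 10, 4, 8, 6, 8, 2)
        square(data, 10, 20, 4, 8, 2, 8, 3)
        vol = volume(data)
        cell = MaskVolume(vol.grid, np.ones_like(data, np.uint8), "cell")
        cell.data[:, :, 0] = 0
        g = build_segment_graph(vol)
        tracks = track_myofibrils(g, boundary_distance_map(cell), nominal_sarcomere_length=200.0)
        assert [t.path for t in tracks] == [[1, 3], [2, 3]]

    def test_early_termination_censored(self):
        data = np.zeros((20, 12, 12), dtype=np.int32)
        square(data, 0, 12, 2, 6, 2, 6, 1)  # ends at z=12 of 20
        square(data, 0, 20, 7, 11, 7, 11, 2)
        vol = volume(data)
        cell = MaskVolume(vol.grid, np.ones_like(data, np.uint8), "cell")
        cell.data[:, 0, :] = 0
        g = build_segment_graph(vol)
        tracks = track_myofibrils(g, boundary_distance_map(cell), nominal_sarcomere_length=200.0)
        assert tracks[0].censored and not tracks[1].censored

    def test_missing_distance_map_rejected(self):
        data = np.zeros((5, 8, 8), dtype=np.int32)
        square(data, 0, 5, 2, 6, 2, 6, 1)
        g = build_segment_graph(volume(data))
        with pytest.raises(TopologyError):
            track_myofibrils(g, None)


def _track(n_sarc, events, censored=False, seed=0):
    n_single = sum(1 for e in events if e.classification == "single")
    return MyofibrilTrack(
        seed_label=seed, path=[seed], events_encountered=list(events),
        sarcomeres_traversed=n_sarc,
        branching_sarcomere_count=min(len(events), n_sarc),
        n_single=n_single, n_multi=len(events) - n_single,
        total_branch_count=sum(e.branch_count for e in events),
        censored=censored,
    )


class TestBranchingStatistics:
    def test_zero_event_case(self):
        stats = branching_statistics([_track(10, [], seed=i) for i in range(3)])
        assert stats["pct_myofibrils_branched"] == 0.0
        assert stats["pct_sarcomeres_branched"] == 0.0
        assert stats["branches_per_10"] == 0.0

    def test_hand_enumeration(self):
        # 5 tracks x 10 sarcomeres; one single event and one 1->3 multi
        single = JunctionEvent(10, "split", "single", (1,), (2, 3), 1)
        multi = JunctionEvent(10, "split", "multi", (4,), (5, 6, 7), 2)
        tracks = [
            _track(10, [single], seed=1),
            _track(10, [multi], seed=2),
            _track(10, [], seed=3),
            _track(10, [], seed=4),
            _track(10, [], seed=5),
        ]
        stats = branching_statistics(tracks)
        assert stats["pct_myofibrils_branched"] == pytest.approx(40.0)
        assert stats["pct_sarcomeres_branched"] == pytest.approx(4.0)
        assert stats["branches_per_10"] == pytest.approx(10 * (1 + 2) / 50)
        assert stats["pct_single"] == pytest.approx(2.0)
        assert stats["pct_multi"] == pytest.approx(2.0)

    def test_branches_per_10_floor(self):
        ev = JunctionEvent(5, "split", "multi", (1,), (2, 3, 4, 5), 3)
        stats = branching_statistics([_track(10, [ev])])
        assert stats["branches_per_10"] >= stats["pct_sarcomeres_branched"] / 10

    def test_censored_tracks_excluded_from_per_track_metrics(self):
        ev = JunctionEvent(5, "split", "single", (1,), (2, 3), 1)
        tracks = [_track(10, [ev], seed=1), _track(4, [], censored=True, seed=2)]
        stats = branching_statistics(tracks)
        assert stats["pct_myofibrils_branched"] == 100.0
        # pooled metrics retain the censored track's pre-exit sarcomeres
        assert stats["pct_sarcomeres_branched"] == pytest.approx(100 / 14)

    def test_all_censored_rejected(self):
        with pytest.raises(TopologyError):
            branching_statistics([_track(5, [], censored=True)])


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_event_recovery(self, seed):
        cfg = small_config(seed=seed, n_exiting=seed % 2)
        labels, cell, srt, gt = generate_muscle_volume(cfg)
        g = build_segment_graph(labels, max_gap=cfg.max_gap)
        detected = sorted(
            (e.z_position, e.type, e.classification, e.parent_labels,
             e.child_labels, e.branch_count)
            for e in g.events
        )
        truth = sorted(
            (e.z_position, e.type, e.classification, e.parent_labels,
             e.child_labels, e.branch_count)
            for e in gt.events
        )
        assert detected == truth

    def test_track_statistics_match_flags(self, branched_volume):
        cfg, labels, cell, srt, gt = branched_volume
        g = build_segment_graph(labels, max_gap=cfg.max_gap)
        tracks = track_myofibrils(g, boundary_distance_map(cell), srt=srt)
        stats = branching_statistics(tracks)
        n_obs = gt.observable_sarcomeres
        assert stats["total_sarcomeres"] == n_obs
        assert stats["pct_sarcomeres_branched"] == pytest.approx(
            100.0 * (gt.per_sarcomere_flags > 0).sum() / n_obs
        )
        assert stats["branches_per_10"] == pytest.approx(
            10.0 * sum(e.branch_count for e in gt.events) / n_obs
        )

    def test_split_merge_duality_under_reversal(self, branched_volume):
        cfg, labels, cell, srt, gt = branched_volume
        fwd = build_segment_graph(labels, max_gap=cfg.max_gap)
        rev_vol = LabeledVolume(labels.grid, labels.data[::-1].copy())
        rev = build_segment_graph(rev_vol, max_gap=cfg.max_gap)
        assert len(fwd.events) == len(rev.events)
        fwd_counts = sorted((e.classification, e.branch_count) for e in fwd.events)
        rev_counts = sorted((e.classification, e.branch_count) for e in rev.events)
        assert fwd_counts == rev_counts
        n_split_fwd = sum(e.type == "split" for e in fwd.events)
        n_merge_rev = sum(e.type == "merge" for e in rev.events)
        assert n_split_fwd == n_merge_rev
        # pooled branching statistics are invariant under reversal
        dist = boundary_distance_map(cell)
        rev_srt = MaskVolume(srt.grid, srt.data[::-1].copy(), "SRT")
        s_fwd = branching_statistics(track_myofibrils(fwd, dist, srt=srt))
        s_rev = branching_statistics(track_myofibrils(rev, dist[::-1].copy(), srt=rev_srt))
        for key in ("pct_sarcomeres_branched", "branches_per_10", "total_sarcomeres"):
            assert s_fwd[key] == pytest.approx(s_rev[key])

    def test_event_distances_extracted(self, branched_volume):
        cfg, labels, cell, srt, gt = branched_volume
        g = build_segment_graph(labels, max_gap=cfg.max_gap)
        dist = boundary_distance_map(cell)
        tracks = track_myofibrils(g, dist, srt=srt)
        d = event_boundary_distances(tracks, g, dist)
        assert len(d) > 0
        assert (d > 0).all()
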