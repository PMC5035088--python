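"""Lineage tracking: costs, the greedy constrained solver, series chaining."""

import itertools

import numpy as np
import pytest

from mmtrace.synthetic import GrowthParams, SceneConfig, generate_stack
from mmtrace.tracking import (
    DetectedCell,
    TrackingCosts,
    TrackingParams,
    build_costs,
    solve_assignment,
    track_series,
)

PX = 0.065


def _cell(frame, top, bottom, channel=0):
    return DetectedCell(
        frame=frame,
        channel=channel,
        top_px=top,
        bottom_px=bottom,
        length_um=(bottom - top) * PX,
    )


def brute_force_optimum(costs: TrackingCosts, J: int, K: int):
    """Exhaustive minimum over all feasible (monotone, one-fate) assignments.

    Assign frame-t cells in order; S/D links must use strictly increasing
    daughter indices (non-crossing); every unclaimed frame-t+1 cell is N.
    Returns (best_cost, frozenset of ('S', j, k) / ('D', j, k) links).
    """
    best = [np.inf, None]

    def recurse(j, next_k, used_k, links, cost):
        if cost >= best[0]:
            return
        if j == J:
            total = cost + costs.new_cost * (K - len(used_k))
            if total < best[0]:
                best[0] = total
                best[1] = frozenset(links)
            return
        # lost
        recurse(j + 1, next_k, used_k, links, cost + costs.lost_cost)
        # same
        for k in range(next_k, K):
            recurse(
                j + 1, k + 1, used_k | {k},
                links + [("S", j, k)], cost + costs.same[j, k],
            )
        # divide into (k, k+1)
        for k in range(next_k, K - 1):
            c = costs.division[j, k]
            if np.isfinite(c):
                recurse(
                    j + 1, k + 2, used_k | {k, k + 1},
                    links + [("D", j, k)], cost + c,
                )

    recurse(0, 0, frozenset(), [], 0.0)
    return best[0], best[1]


def _assignment_links(assignment):
    links = {("S", j, k) for j, k in assignment.same_links}
    links |= {("D", j, k) for j, k in assignment.division_pairs}
    return frozenset(links)


class TestBuildCosts:
    def test_identical_lists_make_diagonal_cheapest(self):
        cells = [_cell(0, 10, 40), _cell(0, 50, 85), _cell(0, 95, 140)]
        nxt = [_cell(1, 10, 40), _cell(1, 50, 85), _cell(1, 95, 140)]
        costs = build_costs(cells, nxt, pixel_size_um=PX)
        for j in range(3):
            assert np.argmin(costs.same[j]) == j
            assert costs.same[j, j] == pytest.approx(0.0, abs=1e-9)

    def test_division_cheaper_than_same_for_split_cell(self):
        """A 4 um cell matched against an adjacent 2.1 + 1.9 um pair at the
        same span prefers the division fate."""
        parent = [_cell(0, 100, 100 + int(4.0 / PX))]
        top_len = int(2.1 / PX)
        daughters = [
            _cell(1, 100, 100 + top_len),
            _cell(1, 100 + top_len, 100 + int(4.0 / PX)),
        ]
        costs = build_costs(parent, daughters, pixel_size_um=PX)
        assert costs.division[0, 0] < costs.same[0, 0]
        assert costs.division[0, 0] < costs.same[0, 1]

    def test_empty_previous_frame_allowed(self):
        costs = build_costs([], [_cell(1, 10, 40)], pixel_size_um=PX)
        assert costs.same.shape == (0, 1)


class TestSolveAssignment:
    def test_single_identical_cell_is_same(self):
        cells = [_cell(0, 10, 40)]
        nxt = [_cell(1, 10, 40)]
        costs = build_costs(cells, nxt, pixel_size_um=PX)
        a = solve_assignment(costs, 1, 1)
        assert a.same[0, 0] == 1
        assert not a.division.any() and not a.new.any() and not a.lost.any()

    def test_division_fate_chosen_for_daughter_pair(self):
        parent = [_cell(0, 100, 161)]
        daughters = [_cell(1, 100, 130), _cell(1, 130, 161)]
        costs = build_costs(parent, daughters, pixel_size_um=PX)
        a = solve_assignment(costs, 1, 2)
        assert a.division_pairs == [(0, 0)]
        assert a.division[0, 0] == 1 and a.division[0, 1] == 1

    def test_all_new_when_no_previous_cells(self):
        costs = build_costs([], [_cell(1, 10, 40), _cell(1, 50, 80)],
                            pixel_size_um=PX)
        a = solve_assignment(costs, 0, 2)
        assert a.new.sum() == 2

    @staticmethod
    def _random_costs(rng, J, K):
        same = rng.uniform(0, 1, size=(J, K))
        division = np.full((J, K), np.inf)
        if K >= 2:
            division[:, : K - 1] = rng.uniform(0, 1.5, size=(J, K - 1))
        return TrackingCosts(same=same, division=division, new_cost=2.0, lost_cost=2.0)

    def test_greedy_near_optimal_on_small_instances(self):
        """Greedy total cost within 10 % (plus epsilon) of the exhaustive
        optimum, identical fate structure in >= 90 % of 500 instances."""
        rng = np.random.default_rng(123)
        identical = 0
        n = 500
        for _ in range(n):
            J, K = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            costs = self._random_costs(rng, J, K)
            greedy = solve_assignment(costs, J, K)
            optimum, opt_links = brute_force_optimum(costs, J, K)
            assert greedy.total_cost <= 1.10 * optimum + 1e-9
            if _assignment_links(greedy) == opt_links:
                identical += 1
        assert identical / n >= 0.90

    def test_fate_completeness_and_non_crossing(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            J, K = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            costs = self._random_costs(rng, J, K)
            a = solve_assignment(costs, J, K)
            # each frame-t cell has exactly one fate
            for j in range(J):
                n_links = a.same[j].sum() + (a.division[j].sum() // 2)
                assert n_links + a.lost[j] == 1
            # each frame-t+1 cell has exactly one origin
            for k in range(K):
                assert a.same[:, k].sum() + a.division[:, k].sum() + a.new[k] == 1
            # divisions always produce exactly two daughters
            for j, k in a.division_pairs:
                assert a.division[j, k] == 1 and a.division[j, k + 1] == 1
            # non-crossing
            links = sorted(
                a.same_links
                + [(j, k) for j, k in a.division_pairs]
                + [(j, k + 1) for j, k in a.division_pairs]
            )
            for (j1, k1), (j2, k2) in itertools.combinations(links, 2):
                if j1 < j2:
                    assert k1 < k2


class TestTrackSeries:
    def test_single_cell_single_track_no_divisions(self):
        per_frame = [[_cell(f, 20, 60)] for f in range(10)]
        tree = track_series({0: per_frame}, times_h=np.arange(10) * 0.1,
                            pixel_size_um=PX)
        assert len(tree.tracks) == 1
        assert not tree.divisions
        assert tree.tracks[0].end_fate == "end"

    def test_flushed_cell_track_ends_lost(self):
        per_frame = [[_cell(f, 20, 60)] if f < 5 else [] for f in range(10)]
        tree = track_series({0: per_frame}, times_h=np.arange(10) * 0.1,
                            pixel_size_um=PX)
        track = tree.tracks[0]
        assert track.end_fate == "lost"
        assert track.last_frame == 4

    def test_scripted_division_recovered(self):
        """One cell grows, splits at frame 5; tracker records the division."""
        per_frame = []
        for f in range(5):
            per_frame.append([_cell(f, 100, 130 + 6 * f)])
        for f in range(5, 10):
            mid = 100 + (30 + 6 * 4) // 2
            per_frame.append([_cell(f, 100, mid), _cell(f, mid, 130 + 6 * 4)])
        tree = track_series({0: per_frame}, times_h=np.arange(10) * 0.1,
                            pixel_size_um=PX)
        assert len(tree.divisions) == 1
        rec = tree.divisions[0]
        assert rec.frame == 5
        parent = tree.tracks[rec.parent_track]
        assert parent.daughter_tracks == list(rec.daughter_tracks)
        assert all(tree.tracks[d].birth_known for d in rec.daughter_tracks)

    def test_simulator_division_count_recovered_from_truth_extents(self):
        """Tracking the simulator's own noise-free extents recovers the
        scripted division count within 5 % over several scenes."""
        total_auto = total_true = 0
        for seed in (31, 32, 33):
            config = SceneConfig(
                n_channels=4, width_px=200, n_frames=80, seed=seed, phase_px=28.0
            )
            _series, truth = generate_stack(config, GrowthParams())
            detections = {
                ch: [
                    [
                        _cell(f, t - config.array_top, b - config.array_top, ch)
                        for _cid, t, b in truth.extents[f][ch]
                    ]
                    for f in range(config.n_frames)
                ]
                for ch in range(config.n_channels)
            }
            times = np.arange(config.n_frames) * config.dt_h
            tree = track_series(detections, times_h=times, pixel_size_um=PX)
            total_auto += len(tree.divisions)
            total_true += truth.scripted_division_count()
        assert abs(total_auto - total_true) <= 0.05 * total_true

    def test_every_sighting_belongs_to_exactly_one_track(self, small_scene,
                                                         small_scene_analysis):
        _config, _series, _truth = small_scene
        tree = small_scene_analysis.tree
        seen = set()
        for track in tree.tracks.values():
            frames = [s.frame for s in track.sightings]
            assert frames == sorted(frames)
            for s in track.sightings:
                key = (s.frame, s.channel, s.top_px, s.bottom_px)
                assert key not in seen
                seen.add(key)
        assert len(seen) == tree.n_sightings

    def test_divisions_always_have_two_daughters(self, small_scene_analysis):
        tree = small_scene_analysis.tree
        for rec in tree.divisions:
            assert len(rec.daughter_tracks) == 2
            parent = tree.tracks[rec.parent_track]
            assert parent.end_fate == "division"
            assert len(parent.daughter_tracks) == 2

    def test_detection_dropout_errors_stay_near_leaves(self):
        """Deleting random sightings induces tracking errors that sit near
        track ends (the lineage tree's leaves), not deep inside tracks."""
        config = SceneConfig(
            n_channels=4, width_px=200, n_frames=80, seed=41, phase_px=28.0
        )
        _series, truth = generate_stack(config, GrowthParams())
        rng = np.random.default_rng(99)
        detections = {}
        for ch in range(config.n_channels):
            per_frame = []
            for f in range(config.n_frames):
                cells = [
                    _cell(f, t - config.array_top, b - config.array_top, ch)
                    for _cid, t, b in truth.extents[f][ch]
                ]
                # 2 % dropout of individual sightings
                cells = [c for c in cells if rng.random() > 0.02]
                per_frame.append(cells)
            detections[ch] = per_frame
        times = np.arange(config.n_frames) * config.dt_h
        tree = track_series(detections, times_h=times, pixel_size_um=PX)
        true_events = {
            (d.channel, d.frame) for d in truth.divisions
        }
        spurious = []
        for rec in tree.divisions:
            matched = any(
                (rec.channel, rec.frame + off) in true_events
                for off in range(-2, 3)
            )
            if not matched:
                spurious.append(rec)
        if spurious:
            near_leaf = 0
            for rec in spurious:
                ends = [tree.tracks[d] for d in rec.daughter_tracks]
                ends.append(tree.tracks[rec.parent_track])
                if any(
                    t.end_fate in ("lost", "end")
                    and t.last_frame - rec.frame <= 2
                    for t in ends
                ) or rec.frame >= config.n_frames - 3:
                    near_leaf += 1
            assert near_leaf / len(spurious) >= 0.7
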