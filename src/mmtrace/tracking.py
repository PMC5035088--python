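"""Frame-to-frame lineage tracking as a constrained assignment problem.

Between consecutive frames every cell of frame t takes exactly one fate:
it stays the *same* cell (S), it *divides* (D) into two adjacent daughters,
or it is *lost* (L, flushed out or lysed); a frame t+1 cell not claimed by S
or D appears *de novo* (N).  Fates carry costs — position deviation from the
track's recent velocity, length deviation from its recent elongation, flat
penalties for N and L that exceed typical movement costs — and the
minimum-cost fate assignment is found under two constraints: every cell has
exactly one fate, and the S/D links are non-crossing (cells cannot swap
order inside a 1D channel).  Because feasible solutions are exactly the
order-preserving fate sequences, the minimisation is solved exactly by a
small dynamic program (see :func:`solve_assignment`).

The exact cost formulas are parameterised design choices of this package
(quadratic position and relative-length deviations, a small division bias,
constant new/lost penalties); all coefficients live in
:class:`TrackingParams` so alternative forms can be dropped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class DetectedCell:
    """One cell sighting: a detected 1D interval within a named channel."""

    frame: int
    channel: int
    top_px: float
    bottom_px: float
    length_um: float
    blackness: float = 0.0
    prominence: float = 0.0
    fluorescence: dict[str, float] = field(default_factory=dict)

    @property
    def center_px(self) -> float:
        return 0.5 * (self.top_px + self.bottom_px)


@dataclass
class TrackingParams:
    """Cost coefficients of the fate assignment.

    Distances are measured in um.  ``new_cost``/``lost_cost`` must exceed
    typical movement costs so N/L stay the fates of last resort.
    ``history_weights`` weight the most recent per-frame velocity and
    elongation observations (newest first) when predicting a track's next
    position and length.
    """

    position_weight: float = 1.0  # per um^2
    length_weight: float = 5.0  # per squared relative deviation
    division_bias: float = 0.2
    asymmetry_weight: float = 0.5
    new_cost: float = 5.0
    lost_cost: float = 5.0
    history_weights: tuple[float, ...] = (4.0, 2.0, 1.0)


@dataclass
class TrackingCosts:
    """Cost matrices for one frame pair: S and D are J x K, N/L are scalars."""

    same: np.ndarray
    division: np.ndarray  # division[j, k] links j to the daughter pair (k, k+1)
    new_cost: float
    lost_cost: float


@dataclass
class Assignment:
    """Solved fates for one frame pair.

    ``same`` and ``division`` are binary J x K matrices (a division marks
    both daughters), ``new`` is length K, ``lost`` length J.  Every frame-t
    cell has exactly one fate and every frame-t+1 cell exactly one origin.
    """

    same: np.ndarray
    division: np.ndarray
    new: np.ndarray
    lost: np.ndarray
    total_cost: float
    division_pairs: list[tuple[int, int]] = field(default_factory=list)
    same_links: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CellTrack:
    """A maximal run of sightings of one physical cell."""

    track_id: int
    channel: int
    sightings: list[DetectedCell] = field(default_factory=list)
    parent_track: int | None = None
    daughter_tracks: list[int] = field(default_factory=list)
    end_fate: str = "open"  # "division" | "lost" | "end"
    birth_known: bool = False

    @property
    def birth_frame(self) -> int:
        return self.sightings[0].frame

    @property
    def last_frame(self) -> int:
        return self.sightings[-1].frame


@dataclass
class DivisionRecord:
    """A division event: parent track ends, two daughter tracks start."""

    channel: int
    frame: int  # frame where the daughters first appear
    parent_track: int
    daughter_tracks: tuple[int, int]


@dataclass
class LineageTree:
    """All tracks and division events of one analysed position."""

    tracks: dict[int, CellTrack] = field(default_factory=dict)
    divisions: list[DivisionRecord] = field(default_factory=list)
    times_h: np.ndarray | None = None

    @property
    def n_sightings(self) -> int:
        return sum(len(t.sightings) for t in self.tracks.values())


class _TrackHistory:
    """Recent velocity (um/frame) and elongation factor of an active track."""

    def __init__(self, weights: tuple[float, ...]):
        self.weights = np.asarray(weights, dtype=float)
        self.velocities: list[float] = []
        self.growth: list[float] = []

    def _ewm(self, values: list[float], default: float) -> float:
        if not values:
            return default
        recent = values[-len(self.weights) :][::-1]
        w = self.weights[: len(recent)]
        return float(np.dot(w, recent) / w.sum())

    def predicted_velocity(self) -> float:
        return self._ewm(self.velocities, 0.0)

    def predicted_growth(self) -> float:
        return self._ewm(self.growth, 1.0)

    def update(self, prev: DetectedCell, new: DetectedCell, pixel_size_um: float):
        self.velocities.append((new.center_px - prev.center_px) * pixel_size_um)
        if prev.length_um > 0:
            self.growth.append(new.length_um / prev.length_um)


def build_costs(
    cells_t: list[DetectedCell],
    cells_t1: list[DetectedCell],
    histories: list[_TrackHistory] | None = None,
    params: TrackingParams | None = None,
    pixel_size_um: float = 1.0,
    step_frames: int = 1,
) -> TrackingCosts:
    """Fate cost matrices for one frame pair.

    ``histories`` supplies per-track velocity/elongation summaries for the
    frame-t cells (cold start: zero velocity, unit growth).  ``step_frames``
    scales the predictions when a skipped frame is bridged, and widens the
    effective movement tolerance accordingly.
    """
    params = params or TrackingParams()
    J, K = len(cells_t), len(cells_t1)
    same = np.zeros((J, K))
    division = np.full((J, K), np.inf)
    pos1 = np.array([c.center_px * pixel_size_um for c in cells_t1])
    len1 = np.array([c.length_um for c in cells_t1])
    pw = params.position_weight / step_frames
    for j, cell in enumerate(cells_t):
        hist = histories[j] if histories else None
        vel = hist.predicted_velocity() if hist else 0.0
        growth = hist.predicted_growth() if hist else 1.0
        pred_pos = cell.center_px * pixel_size_um + vel * step_frames
        pred_len = max(cell.length_um * growth**step_frames, 1e-6)
        for k in range(K):
            dlen = (len1[k] - pred_len) / pred_len
            same[j, k] = pw * (pos1[k] - pred_pos) ** 2 + params.length_weight * dlen**2
        for k in range(K - 1):
            pair_len = len1[k] + len1[k + 1]
            pair_mid = 0.5 * (
                cells_t1[k].top_px + cells_t1[k + 1].bottom_px
            ) * pixel_size_um
            dlen = (pair_len - pred_len) / pred_len
            asym = (len1[k] - len1[k + 1]) / max(pair_len, 1e-6)
            division[j, k] = (
                pw * (pair_mid - pred_pos) ** 2
                + params.length_weight * dlen**2
                + params.asymmetry_weight * asym**2
                + params.division_bias
            )
    return TrackingCosts(
        same=same,
        division=division,
        new_cost=params.new_cost,
        lost_cost=params.lost_cost,
    )


def _compatible(links: list[tuple[int, int]], new_links: list[tuple[int, int]]) -> bool:
    """Non-crossing check: all links of S+D must be jointly monotone."""
    for j, k in new_links:
        for j2, k2 in links:
            if (j - j2) * (k - k2) <= 0:
                return False
    return True


def solve_assignment(costs: TrackingCosts, J: int, K: int) -> Assignment:
    """Minimum-cost fate assignment for one frame pair.

    The one-fate and non-crossing constraints mean a feasible solution is an
    order-preserving sequence: walking frame-t cells top to bottom, each is
    lost or linked (S, or D to an adjacent daughter pair) to daughters at
    strictly increasing positions, and every unclaimed frame-t+1 cell is de
    novo.  That structure admits an exact O(J*K^2) dynamic program over
    (frame-t cell, first available daughter), which this solver implements;
    N and L keep the problem always feasible.  Ties resolve towards linking
    fates and smaller daughter indices (deterministic).
    """
    same_c = np.asarray(costs.same, dtype=float)
    div_c = np.asarray(costs.division, dtype=float)
    c_n = float(costs.new_cost)
    c_l = float(costs.lost_cost)

    # f[j, m]: minimal cost of fates for cells j.. using daughters m..,
    # including c_N for every daughter >= m left unclaimed
    f = np.zeros((J + 1, K + 1))
    f[J, :] = c_n * (K - np.arange(K + 1))
    choice: dict[tuple[int, int], tuple[str, int]] = {}
    for j in range(J - 1, -1, -1):
        for m in range(K, -1, -1):
            best_cost = None
            best = ("L", -1)
            candidates = []
            for k in range(m, K):
                candidates.append(
                    (c_n * (k - m) + same_c[j, k] + f[j + 1, k + 1], ("S", k))
                )
            for k in range(m, K - 1):
                if np.isfinite(div_c[j, k]):
                    candidates.append(
                        (c_n * (k - m) + div_c[j, k] + f[j + 1, k + 2], ("D", k))
                    )
            candidates.append((c_l + f[j + 1, m], ("L", -1)))
            for cost, what in candidates:
                if best_cost is None or cost < best_cost - 1e-12:
                    best_cost, best = cost, what
            f[j, m] = best_cost
            choice[(j, m)] = best

    same = np.zeros((J, K), dtype=int)
    division = np.zeros((J, K), dtype=int)
    new = np.zeros(K, dtype=int)
    lost = np.zeros(J, dtype=int)
    same_links: list[tuple[int, int]] = []
    division_pairs: list[tuple[int, int]] = []
    m = 0
    for j in range(J):
        kind, k = choice[(j, m)]
        if kind == "L":
            lost[j] = 1
        elif kind == "S":
            new[m:k] = 1
            same[j, k] = 1
            same_links.append((j, k))
            m = k + 1
        else:
            new[m:k] = 1
            division[j, k] = division[j, k + 1] = 1
            division_pairs.append((j, k))
            m = k + 2
    new[m:K] = 1
    return Assignment(
        same=same,
        division=division,
        new=new,
        lost=lost,
        total_cost=float(f[0, 0]),
        division_pairs=division_pairs,
        same_links=same_links,
    )


def track_series(
    detections_by_channel: dict[int, list[list[DetectedCell]]],
    times_h: np.ndarray,
    params: TrackingParams | None = None,
    pixel_size_um: float = 1.0,
    present_frames: dict[int, list[int]] | None = None,
) -> LineageTree:
    """Chain per-frame detections of every channel into a lineage tree.

    ``detections_by_channel[ch]`` is a per-frame list (aligned with
    ``times_h``) of top-to-bottom sorted cells.  ``present_frames`` can
    restrict a channel to the frames where its geometry was actually found;
    gaps are bridged as a single step with widened movement tolerance.
    """
    params = params or TrackingParams()
    tree = LineageTree(times_h=np.asarray(times_h, dtype=float))
    next_id = 0
    for channel, per_frame in sorted(detections_by_channel.items()):
        frames = (
            present_frames[channel]
            if present_frames is not None
            else list(range(len(per_frame)))
        )
        active: list[int] = []
        hist: dict[int, _TrackHistory] = {}

        def new_track(cell: DetectedCell, parent: int | None, birth_known: bool):
            nonlocal next_id
            tr = CellTrack(
                track_id=next_id,
                channel=channel,
                sightings=[cell],
                parent_track=parent,
                birth_known=birth_known,
            )
            tree.tracks[next_id] = tr
            hist[next_id] = _TrackHistory(params.history_weights)
            next_id += 1
            return tr.track_id

        prev_frame: int | None = None
        for frame in frames:
            cells = sorted(per_frame[frame], key=lambda c: c.top_px)
            if prev_frame is None:
                active = [new_track(c, None, False) for c in cells]
                prev_frame = frame
                continue
            step = frame - prev_frame
            if step > 1:
                log.warning(
                    "channel %d: bridging %d skipped frame(s) before frame %d",
                    channel,
                    step - 1,
                    frame,
                )
            prev_cells = [tree.tracks[t].sightings[-1] for t in active]
            costs = build_costs(
                prev_cells,
                cells,
                histories=[hist[t] for t in active],
                params=params,
                pixel_size_um=pixel_size_um,
                step_frames=step,
            )
            assignment = solve_assignment(costs, len(prev_cells), len(cells))
            origin: dict[int, int | None] = {}
            for j, k in assignment.same_links:
                tid = active[j]
                hist[tid].update(prev_cells[j], cells[k], pixel_size_um)
                tree.tracks[tid].sightings.append(cells[k])
                origin[k] = tid
            for j, k in assignment.division_pairs:
                parent = active[j]
                tree.tracks[parent].end_fate = "division"
                d1 = new_track(cells[k], parent, True)
                d2 = new_track(cells[k + 1], parent, True)
                tree.tracks[parent].daughter_tracks = [d1, d2]
                tree.divisions.append(
                    DivisionRecord(channel, frame, parent, (d1, d2))
                )
                origin[k] = d1
                origin[k + 1] = d2
            for j in np.flatnonzero(assignment.lost):
                tree.tracks[active[j]].end_fate = "lost"
            for k in np.flatnonzero(assignment.new):
                origin[k] = new_track(cells[k], None, False)
            active = [origin[k] for k in range(len(cells)) if origin.get(k) is not None]
            prev_frame = frame
        for tid in active:
            if tree.tracks[tid].end_fate == "open":
                tree.tracks[tid].end_fate = "end"
    return tree
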