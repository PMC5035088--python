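"""Single-cell read-outs from the lineage tree.

Division times are the spacing of consecutive divisions along a lineage
path: a track born at a division and ending in a division contributes one
event whose duration is the time between those two divisions.  Events whose
implied growth rate mu = ln(2) / t_d falls outside loose physiological
bounds (default 0.01/h < mu < 1.0/h) are discarded as tracking artifacts.
The population growth rate follows as mu = ln(2) / mean(t_d).

Also here: greedy Manhattan-distance pairing of automated vs reference
division events (precision/recall), bounding-box fluorescence with
inter-channel background subtraction, tabular per-sighting export, the
moving-average growth-rate curve, and kymograph rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ChannelGeometry
from .io_stack import Calibration
from .tracking import DetectedCell, LineageTree

log = logging.getLogger(__name__)

DEFAULT_MU_BOUNDS = (0.01, 1.0)  # 1/h


@dataclass
class DivisionEvent:
    """One division with the time since the parent's own birth division."""

    channel: int
    frame: int
    time_h: float
    parent_track: int
    division_time_h: float
    age_frames: int
    daughter_lengths_um: tuple[float, float]

    @property
    def mu_per_h(self) -> float:
        return float(np.log(2) / self.division_time_h)


@dataclass
class GrowthRateResult:
    """Population doubling-time statistics and the implied growth rate."""

    mean_td_h: float
    sd_td_h: float
    n_events: int

    @property
    def mu_per_h(self) -> float:
        return growth_rate(self.mean_td_h)


def growth_rate(mean_td_h: float) -> float:
    """Growth rate mu = ln(2) / t_d in 1/h."""
    if mean_td_h <= 0:
        raise ValueError("doubling time must be positive")
    return float(np.log(2) / mean_td_h)


def division_times(
    tree: LineageTree,
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS,
) -> list[DivisionEvent]:
    """Division events with physiologically plausible division times.

    A track contributes an event when it ends in a division AND its own
    birth was observed as a division (de novo tracks have no measurable
    birth, so their first division is excluded to avoid biased times).
    Events with mu outside ``mu_bounds`` are dropped.
    """
    if tree.times_h is None:
        raise ValueError("tree carries no time base")
    times = tree.times_h
    lo, hi = mu_bounds
    events = []
    for rec in tree.divisions:
        parent = tree.tracks[rec.parent_track]
        if not parent.birth_known:
            continue
        dt_h = float(times[rec.frame] - times[parent.birth_frame])
        if dt_h <= 0:
            continue
        mu = np.log(2) / dt_h
        if not lo < mu < hi:
            continue
        d1 = tree.tracks[rec.daughter_tracks[0]].sightings[0].length_um
        d2 = tree.tracks[rec.daughter_tracks[1]].sightings[0].length_um
        events.append(
            DivisionEvent(
                channel=rec.channel,
                frame=rec.frame,
                time_h=float(times[rec.frame]),
                parent_track=rec.parent_track,
                division_time_h=dt_h,
                age_frames=rec.frame - parent.birth_frame,
                daughter_lengths_um=(d1, d2),
            )
        )
    return events


def division_time_stats(events: list[DivisionEvent]) -> GrowthRateResult:
    """Mean/SD of division times and the implied growth rate."""
    if not events:
        raise ValueError("no division events")
    td = np.array([e.division_time_h for e in events])
    return GrowthRateResult(
        mean_td_h=float(td.mean()), sd_td_h=float(td.std(ddof=1) if td.size > 1 else 0.0),
        n_events=td.size,
    )


def pair_events(
    auto: list[DivisionEvent],
    reference: list[DivisionEvent],
    max_offset_frames: int,
) -> tuple[float, float | None]:
    """Greedy one-to-one matching of division events; precision and recall.

    Events are points (occurrence frame, division age in frames); pairs are
    matched in ascending Manhattan distance, and a pair is admissible only
    when both coordinates differ by at most ``max_offset_frames``.  Recall is
    ``None`` (not applicable) for an empty reference.
    """
    if not reference:
        return (0.0 if auto else 1.0), None
    pairs = []
    for i, a in enumerate(auto):
        for j, r in enumerate(reference):
            df = abs(a.frame - r.frame)
            da = abs(a.age_frames - r.age_frames)
            if df <= max_offset_frames and da <= max_offset_frames:
                pairs.append((df + da, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_r: set[int] = set()
    matched = 0
    for _d, i, j in pairs:
        if i in used_a or j in used_r:
            continue
        used_a.add(i)
        used_r.add(j)
        matched += 1
    precision = matched / len(auto) if auto else 1.0
    recall = matched / len(reference)
    return float(precision), float(recall)


def background_stripes(
    geometry: ChannelGeometry, central_fraction: float = 0.5
) -> list[tuple[int, int]]:
    """Central portions of the inter-channel gaps used as fluorescence background."""
    stripes = []
    boxes = geometry.channel_boxes
    for (l0, r0), (l1, _r1) in zip(boxes, boxes[1:]):
        gap = l1 - r0
        if gap < 2:
            continue
        margin = int(round(gap * (1 - central_fraction) / 2))
        lo, hi = r0 + margin, l1 - margin
        if hi > lo:
            stripes.append((lo, hi))
    return stripes


def cell_fluorescence(
    cell: DetectedCell,
    fluor_frame: np.ndarray | None,
    geometry: ChannelGeometry,
    channel_index: int,
) -> float | None:
    """Background-corrected bounding-box fluorescence of one sighting.

    The raw value is the mean over the cell's bounding box (channel width x
    [top, bottom)); the background is the mean of the device structure
    between the growth channels at the same rows, and is subtracted.
    Returns ``None`` when no fluorescence frame exists at this time point.
    """
    if fluor_frame is None:
        return None
    frame = np.asarray(fluor_frame, dtype=float)
    left, right = geometry.channel_boxes[channel_index]
    top = geometry.array_top + int(cell.top_px)
    bottom = geometry.array_top + int(cell.bottom_px)
    value = float(frame[top:bottom, left:right].mean())
    stripes = background_stripes(geometry)
    if stripes:
        bg = float(
            np.mean(np.concatenate([frame[top:bottom, lo:hi].ravel() for lo, hi in stripes]))
        )
    else:
        bg = 0.0
    return value - bg


def growth_rate_curve(
    events: list[DivisionEvent],
    window_events: int = 25,
    min_events: int = 5,
    bin_width_h: float = 1.0,
) -> pd.DataFrame:
    """Moving-average growth rate over division events, binned in time.

    The rolling mean runs over ``window_events`` consecutive events ordered
    by occurrence time; the curve is then sampled per time bin and left
    undefined (NaN) for bins holding fewer than ``min_events`` events, so
    sparse stretches cannot produce spurious rates.
    """
    if not events:
        return pd.DataFrame(columns=["time_h", "mu_per_h", "n_events"])
    df = pd.DataFrame(
        {
            "time_h": [e.time_h for e in events],
            "td_h": [e.division_time_h for e in events],
        }
    ).sort_values("time_h")
    df["td_roll"] = df["td_h"].rolling(window_events, min_periods=1).mean()
    df["bin"] = (df["time_h"] // bin_width_h).astype(int)
    out = (
        df.groupby("bin")
        .agg(time_h=("time_h", "mean"), td=("td_roll", "last"), n_events=("td_h", "size"))
        .reset_index(drop=True)
    )
    out["mu_per_h"] = np.log(2) / out["td"]
    out.loc[out["n_events"] < min_events, "mu_per_h"] = np.nan
    return out[["time_h", "mu_per_h", "n_events"]]


TABLE_COLUMNS = [
    "position",
    "channel",
    "frame",
    "time_h",
    "track_id",
    "parent_track",
    "top_px",
    "bottom_px",
    "length_um",
    "blackness",
    "prominence",
    "fate",
]


def results_table(
    tree: LineageTree,
    calibration: Calibration,
    position_id: str = "pos0",
) -> pd.DataFrame:
    """One row per cell sighting with lineage links and measurements.

    Frames are reported 1-based in the output (internal indices are
    0-based).  The ``fate`` column marks the last sighting of each track
    with how it ended; earlier sightings carry ``same``.  Fluorescence
    columns appear when sightings carry fluorescence values.
    """
    rows = []
    times = tree.times_h
    fluor_names = sorted(
        {name for tr in tree.tracks.values() for s in tr.sightings for name in s.fluorescence}
    )
    for tid in sorted(tree.tracks):
        track = tree.tracks[tid]
        for i, s in enumerate(track.sightings):
            last = i == len(track.sightings) - 1
            fate = track.end_fate if last else "same"
            row = {
                "position": position_id,
                "channel": track.channel,
                "frame": s.frame + 1,
                "time_h": float(times[s.frame]) if times is not None else np.nan,
                "track_id": tid,
                "parent_track": -1 if track.parent_track is None else track.parent_track,
                "top_px": s.top_px,
                "bottom_px": s.bottom_px,
                "length_um": s.length_um,
                "blackness": s.blackness,
                "prominence": s.prominence,
                "fate": fate,
            }
            for name in fluor_names:
                row[f"fluor_{name}"] = s.fluorescence.get(name, np.nan)
            rows.append(row)
    columns = TABLE_COLUMNS + [f"fluor_{n}" for n in fluor_names]
    return pd.DataFrame(rows, columns=columns)


def export_table(
    tree: LineageTree,
    calibration: Calibration,
    out_path,
    position_id: str = "pos0",
) -> Path:
    """Write the per-sighting results table as tab-separated UTF-8."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df = results_table(tree, calibration, position_id)
    df.to_csv(out_path, sep="\t", index=False, encoding="utf-8")
    return out_path


def render_kymograph(
    channel_frames: list[np.ndarray],
    tree: LineageTree,
    out_path,
    channel: int | None = None,
) -> Path:
    """Kymograph: channel crops tiled in frame order with lineage overlay.

    Each track draws one polyline through its sighting centroids (one colour
    per track); a division is marked by connecting the parent's last
    centroid to both daughters' first centroids.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not channel_frames:
        raise ValueError("need at least one channel frame")
    height = max(f.shape[0] for f in channel_frames)
    width = max(f.shape[1] for f in channel_frames)
    tiles = np.full((height, width * len(channel_frames)), np.nan)
    for i, f in enumerate(channel_frames):
        tiles[: f.shape[0], i * width : i * width + f.shape[1]] = f

    fig, ax = plt.subplots(
        figsize=(max(4, len(channel_frames) * 0.12), max(2, height / 60))
    )
    ax.imshow(tiles, cmap="gray", aspect="auto", interpolation="nearest")
    cmap = plt.get_cmap("tab20")

    def centroid(s: DetectedCell) -> tuple[float, float]:
        return (s.frame * width + width / 2, 0.5 * (s.top_px + s.bottom_px))

    tracks = [
        t
        for t in tree.tracks.values()
        if channel is None or t.channel == channel
    ]
    for track in tracks:
        pts = [centroid(s) for s in track.sightings]
        color = cmap(track.track_id % 20)
        if track.parent_track is not None and track.parent_track in tree.tracks:
            pts.insert(0, centroid(tree.tracks[track.parent_track].sightings[-1]))
        xs, ys = zip(*pts)
        ax.plot(xs, ys, "-", color=color, linewidth=1.0)
        if track.end_fate == "division":
            ax.plot(*centroid(track.sightings[-1]), "o", color=color, markersize=3)
    ax.set_xlabel("frame tiles")
    ax.set_ylabel("channel position (px)")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
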