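"""End-to-end orchestration: registration -> rotation -> channels -> cells -> tracking.

The per-frame stages (2-4) are independent of each other across frames and
may run in a process pool; results are identical to serial execution because
every stage is a pure function of the frame and the frame-0 reference.
Tracking is serial by nature (it chains frame pairs).

Frames where the channel array cannot be found are skipped with a warning
rather than aborting the run; the tracker bridges such gaps as a single
step with widened movement tolerance.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cells import DetectionParams, detect_cells
from .channels import (
    ChannelDetectionParams,
    ChannelGeometry,
    detect_frame_boxes,
    detect_geometry,
    match_channels,
)
from .errors import EstimationFailedError, MMTraceError, StructureNotFoundError
from .io_stack import FrameSeries
from .quantify import cell_fluorescence
from .registration import (
    ShiftVector,
    apply_shift,
    estimate_rotation,
    estimate_shift,
    rotate_image,
)
from .tracking import DetectedCell, LineageTree, TrackingParams, track_series

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All stage parameters of one analysis run."""

    registration: bool = True
    rotation_mode: str = "first"  # "first" | "per-frame" | "off"
    n_strips: int = 16
    channel: ChannelDetectionParams = field(default_factory=ChannelDetectionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    workers: int = 1
    keep_crop_channels: tuple[int, ...] = ()  # canonical ids to keep for kymographs


@dataclass
class StageCounters:
    """Per-stage tallies for the run summary."""

    frames_total: int = 0
    frames_processed: int = 0
    frames_skipped: int = 0
    channels: int = 0
    cell_sightings: int = 0
    divisions: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AnalysisResult:
    tree: LineageTree
    geometry: ChannelGeometry
    rotation_deg: float
    shifts: list[ShiftVector]
    counters: StageCounters
    warnings: list[str] = field(default_factory=list)
    channel_crops: dict[int, list[np.ndarray | None]] = field(default_factory=dict)


def _frame_payload(
    frame: np.ndarray,
    shift: ShiftVector,
    theta_rad: float,
    canonical: ChannelGeometry,
    channel_params: ChannelDetectionParams,
    detection_params: DetectionParams,
    pixel_size_um: float,
    keep_channels: tuple[int, ...],
):
    """Stages 2-4 for one frame.  Pure function -> safe to parallelise."""
    frame = np.asarray(frame, dtype=float)
    if shift.dx or shift.dy:
        frame = apply_shift(frame, -shift)
    if theta_rad:
        frame = rotate_image(frame, -theta_rad)
    try:
        geom = detect_frame_boxes(frame, canonical, channel_params)
    except StructureNotFoundError as exc:
        return shift, None, {}, {}, str(exc)
    except MMTraceError:
        # registration already aligned the frame; reuse the canonical boxes
        geom = canonical
    mapping = match_channels(
        geom.channel_boxes, canonical.channel_boxes, canonical.interval_px
    )
    cells: dict[int, list] = {}
    crops: dict[int, np.ndarray] = {}
    from .io_stack import Calibration

    cal = Calibration(pixel_size_um=pixel_size_um, frame_interval_min=1.0)
    # the stack is registered, so the canonical array rows apply to every
    # frame; per-frame geometry contributes the channel x positions only
    for box_idx, cid in mapping.items():
        left, right = geom.channel_boxes[box_idx]
        crop = frame[canonical.array_top : canonical.array_bottom, left:right]
        accepted = detect_cells(crop, detection_params, cal)
        cells[cid] = [
            (
                cand.top_px,
                cand.bottom_px,
                cand.length_um,
                cand.blackness,
                cand.prominence,
            )
            for cand in accepted
        ]
        if cid in keep_channels:
            crops[cid] = crop
    return shift, geom, cells, crops, None


def _payload_star(args):
    return _frame_payload(*args)


def analyze_series(
    series: FrameSeries, params: PipelineParams | None = None
) -> AnalysisResult:
    """Run the full pipeline on one frame series and return the lineage tree."""
    params = params or PipelineParams()
    counters = StageCounters(frames_total=series.n_frames)
    warnings: list[str] = []

    reference = np.asarray(series.frames[0], dtype=float)
    theta = 0.0
    if params.rotation_mode != "off":
        try:
            theta = estimate_rotation(reference, n_strips=params.n_strips).theta_rad
        except (EstimationFailedError, ValueError) as exc:
            warnings.append(f"rotation estimation failed, using 0: {exc}")
    ref_rotated = rotate_image(reference, -theta) if theta else reference
    canonical = detect_geometry(ref_rotated, params.channel)
    counters.channels = canonical.n_channels
    pixel_size = series.calibration.pixel_size_um

    # drift is continuous, so each frame's shift is searched near the
    # previous frame's; this also resolves the periodic-comb ambiguity of
    # the correlation peak (peaks repeat every channel interval)
    shift_list: list[ShiftVector] = []
    if params.registration:
        radius = max(5, int(canonical.interval_px / 3))
        prev = ShiftVector(0, 0)
        for f in range(series.n_frames):
            prev = estimate_shift(
                reference, series.frames[f], center=prev, radius=radius
            )
            shift_list.append(prev)
    else:
        shift_list = [ShiftVector(0, 0)] * series.n_frames

    jobs = [
        (
            series.frames[f],
            shift_list[f],
            theta,
            canonical,
            params.channel,
            params.detection,
            pixel_size,
            params.keep_crop_channels,
        )
        for f in range(series.n_frames)
    ]
    if params.workers > 1:
        with ProcessPoolExecutor(max_workers=params.workers) as pool:
            results = list(pool.map(_payload_star, jobs, chunksize=8))
    else:
        results = [_frame_payload(*job) for job in jobs]

    detections: dict[int, list[list[DetectedCell]]] = {
        cid: [[] for _ in range(series.n_frames)]
        for cid in range(canonical.n_channels)
    }
    present: dict[int, list[int]] = {cid: [] for cid in range(canonical.n_channels)}
    crops: dict[int, list[np.ndarray | None]] = {
        cid: [None] * series.n_frames for cid in params.keep_crop_channels
    }
    shifts: list[ShiftVector] = []
    fluor_corrected: dict[int, dict[str, np.ndarray]] = {}

    for f, (shift, geom, cells, frame_crops, error) in enumerate(results):
        shifts.append(shift)
        if error is not None:
            counters.frames_skipped += 1
            warnings.append(f"frame {f}: skipped ({error})")
            continue
        counters.frames_processed += 1
        # register fluorescence frames identically to the phase frame
        fl = {}
        for name, seq in series.fluorescence.items():
            if seq[f] is not None:
                img = np.asarray(seq[f], dtype=float)
                if shift.dx or shift.dy:
                    img = apply_shift(img, -shift)
                if theta:
                    img = rotate_image(img, -theta)
                fl[name] = img
        if fl:
            fluor_corrected[f] = fl
        for cid, rows in cells.items():
            present[cid].append(f)
            sightings = []
            for top, bottom, length_um, blackness, prominence in rows:
                cell = DetectedCell(
                    frame=f,
                    channel=cid,
                    top_px=top,
                    bottom_px=bottom,
                    length_um=length_um,
                    blackness=blackness,
                    prominence=prominence,
                )
                for name, img in fl.items():
                    value = cell_fluorescence(cell, img, canonical, cid)
                    if value is not None:
                        cell.fluorescence[name] = value
                sightings.append(cell)
            detections[cid][f] = sightings
            counters.cell_sightings += len(sightings)
        for cid, crop in frame_crops.items():
            crops[cid][f] = crop

    tree = track_series(
        detections,
        times_h=series.times_h(),
        params=params.tracking,
        pixel_size_um=pixel_size,
        present_frames=present,
    )
    counters.divisions = len(tree.divisions)
    for w in warnings:
        log.warning(w)
    return AnalysisResult(
        tree=tree,
        geometry=canonical,
        rotation_deg=float(np.degrees(theta)),
        shifts=shifts,
        counters=counters,
        warnings=warnings,
        channel_crops=crops,
    )


def write_run_summary(
    out_path,
    counters: StageCounters,
    config: dict,
    warnings: list[str],
) -> Path:
    """JSON run summary: echoed configuration, per-stage counters, warnings."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(
        json.dumps(
            {"config": config, "counters": counters.as_dict(), "warnings": warnings},
            indent=2,
            default=str,
        )
    )
    return out_path
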