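"""Reading and writing image stacks; the uniform frame-series abstraction.

Real mother-machine data arrives as (OME-)TIFF stacks with a pixel size in
um/px and either a fixed frame interval or per-frame timestamps.  Synthetic
stacks produced by :mod:`mmtrace.synthetic` round-trip through the same
reader.  Calibration found in OME-XML metadata wins over configuration
values; configuration is the fallback, and a hard error is raised when
neither is available (the 1 um cell-length filter is meaningless without a
pixel size).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError

__all__ = ["Calibration", "FrameSeries", "load_stack", "write_stack", "subsample"]


@dataclass
class Calibration:
    """Spatial and temporal calibration of a frame series.

    ``pixel_size_um`` is um per pixel.  Time is given either as a fixed
    ``frame_interval_min`` (minutes between frames) or as explicit
    ``timestamps_h`` (hours, strictly increasing); explicit timestamps win.
    """

    pixel_size_um: float
    frame_interval_min: float | None = None
    timestamps_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.timestamps_h is not None:
            self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
            if self.timestamps_h.size and np.any(np.diff(self.timestamps_h) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        elif self.frame_interval_min is None:
            raise ValueError("either frame_interval_min or timestamps_h is required")
        elif self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    def times_h(self, n_frames: int) -> np.ndarray:
        """Acquisition times in hours for frames 0..n_frames-1."""
        if self.timestamps_h is not None:
            if self.timestamps_h.size < n_frames:
                raise ValueError("fewer timestamps than frames")
            return self.timestamps_h[:n_frames]
        return np.arange(n_frames) * self.frame_interval_min / 60.0


@dataclass
class FrameSeries:
    """Ordered grayscale frames of one stage position plus calibration.

    ``fluorescence`` maps a channel name to a per-frame list aligned with
    ``frames``; time points without an acquisition hold ``None`` (missing
    fluorescence is recorded as absent, never interpolated).
    """

    frames: np.ndarray  # (T, H, W) float array
    calibration: Calibration
    fluorescence: dict[str, list[np.ndarray | None]] = field(default_factory=dict)
    position_id: str = "pos0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        t, h, w = self.frames.shape
        for name, seq in self.fluorescence.items():
            if len(seq) != t:
                raise ValueError(f"fluorescence {name!r} not aligned with frames")
            for fr in seq:
                if fr is not None and fr.shape != (h, w):
                    raise ValueError(f"fluorescence {name!r} shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_h(self) -> np.ndarray:
        return self.calibration.times_h(self.n_frames)


_OME_PX = re.compile(r'PhysicalSizeX="([0-9.eE+-]+)"')
_OME_DT = re.compile(r'TimeIncrement="([0-9.eE+-]+)"')


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def load_stack(
    path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    fluor_channels: tuple[str, ...] = (),
    position_id: str | None = None,
) -> FrameSeries:
    """Load a (OME-)TIFF stack into a :class:`FrameSeries`.

    Pages are taken in order as time points.  Calibration precedence:
    OME-XML metadata, then a sidecar ``<name>.meta.json`` written by
    :func:`write_stack`, then the ``pixel_size_um``/``frame_interval_min``
    arguments.  Fluorescence channels are read from companion files listed in
    the sidecar; frames missing from a channel's schedule stay ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            ome = tf.ome_metadata
    except Exception as exc:  # pragma: no cover - corrupt input
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise IOError(f"expected a grayscale stack, got shape {frames.shape}")

    meta: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())

    px = pixel_size_um
    dt = frame_interval_min
    timestamps = meta.get("timestamps_h")
    if meta.get("pixel_size_um"):
        px = float(meta["pixel_size_um"])
    if meta.get("frame_interval_min"):
        dt = float(meta["frame_interval_min"])
    if ome:
        m = _OME_PX.search(ome)
        if m:
            px = float(m.group(1))
        m = _OME_DT.search(ome)
        if m:
            dt = float(m.group(1))
    if px is None:
        raise ConfigurationError(
            "pixel size not present in metadata and no override supplied"
        )
    if dt is None and timestamps is None:
        raise ConfigurationError(
            "frame interval/timestamps not present in metadata and no override supplied"
        )
    cal = Calibration(
        pixel_size_um=px,
        frame_interval_min=dt,
        timestamps_h=None if timestamps is None else np.asarray(timestamps),
    )

    fluorescence: dict[str, list[np.ndarray | None]] = {}
    recorded = meta.get("fluorescence", {})
    names = fluor_channels or tuple(recorded)
    for name in names:
        entry = recorded.get(name)
        if entry is None:
            continue
        fpath = path.parent / entry["file"]
        pages = tifffile.imread(fpath)
        if pages.ndim == 2:
            pages = pages[None]
        seq: list[np.ndarray | None] = [None] * frames.shape[0]
        for page, idx in zip(pages, entry["frame_indices"]):
            seq[idx] = np.asarray(page, dtype=float)
        fluorescence[name] = seq

    return FrameSeries(
        frames=frames,
        calibration=cal,
        fluorescence=fluorescence,
        position_id=position_id or meta.get("position_id", "pos0"),
    )


def write_stack(series: FrameSeries, path) -> Path:
    """Write a frame series as TIFF plus a calibration sidecar.

    Fluorescence channels go to companion TIFFs holding only the acquired
    pages; the sidecar records their frame indices so :func:`load_stack` can
    restore the gaps.  Pixel data are written unchanged (round-trip
    bit-identical).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.frames)
    meta: dict = {
        "pixel_size_um": series.calibration.pixel_size_um,
        "frame_interval_min": series.calibration.frame_interval_min,
        "position_id": series.position_id,
        "fluorescence": {},
    }
    if series.calibration.timestamps_h is not None:
        meta["timestamps_h"] = list(map(float, series.calibration.timestamps_h))
    for name, seq in series.fluorescence.items():
        idx = [i for i, fr in enumerate(seq) if fr is not None]
        fname = f"{path.stem}.{name}.tif"
        tifffile.imwrite(path.parent / fname, np.stack([seq[i] for i in idx]))
        meta["fluorescence"][name] = {"file": fname, "frame_indices": idx}
    _meta_path(path).write_text(json.dumps(meta))
    return path


def subsample(series: FrameSeries, stride: int) -> FrameSeries:
    """Keep frames 0, stride, 2*stride, ... mimicking a longer imaging interval.

    The frame interval is scaled by ``stride`` (or timestamps subsampled), so
    downstream time-based quantities stay physically correct.
    """
    if int(stride) != stride or stride < 1:
        raise ValueError("stride must be a positive integer")
    stride = int(stride)
    if stride == 1:
        return series
    cal = series.calibration
    new_cal = Calibration(
        pixel_size_um=cal.pixel_size_um,
        frame_interval_min=None
        if cal.frame_interval_min is None
        else cal.frame_interval_min * stride,
        timestamps_h=None if cal.timestamps_h is None else cal.timestamps_h[::stride],
    )
    return FrameSeries(
        frames=series.frames[::stride],
        calibration=new_cal,
        fluorescence={k: v[::stride] for k, v in series.fluorescence.items()},
        position_id=series.position_id,
    )
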