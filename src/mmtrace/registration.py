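"""Frame registration and orientation correction.

Stage drift is corrected per frame against the first frame of the series by
cross-correlating 1D mean-intensity profiles (never the full 2D image): the
horizontal profiles give dx, the vertical profiles dy.  The global rotation
of the channel array is estimated by slicing the image into vertical strips,
differencing each strip's smoothed vertical profile, cross-correlating
adjacent difference profiles, rejecting outlier shifts more than two
standard deviations from the median, and converting the mean surviving shift
into an angle theta = arctan(mean shift / strip width).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EstimationFailedError
from .signal_core import (
    HORIZONTAL,
    VERTICAL,
    mean_profile,
    smooth,
    xcorr_argmax,
    xcorr_argmax_subpixel,
)

log = logging.getLogger(__name__)

MAX_PLAUSIBLE_ROTATION_DEG = 15.0


@dataclass(frozen=True)
class ShiftVector:
    """Integer-pixel displacement of a frame relative to the reference."""

    dx: int
    dy: int

    def __neg__(self) -> "ShiftVector":
        return ShiftVector(-self.dx, -self.dy)


@dataclass
class RotationEstimate:
    """Rotation angle with per-strip diagnostics.

    ``strip_shifts`` holds the shift of each adjacent strip pair,
    ``kept_mask`` marks the shifts surviving the 2-sigma-from-median outlier
    rule, and ``strip_width`` is d = W / N in pixels.
    """

    theta_rad: float
    strip_shifts: np.ndarray
    kept_mask: np.ndarray
    strip_width: float

    @property
    def theta_deg(self) -> float:
        return float(np.degrees(self.theta_rad))


def estimate_shift(
    reference: np.ndarray,
    frame: np.ndarray,
    center: ShiftVector | None = None,
    radius: int | None = None,
) -> ShiftVector:
    """Displacement of ``frame`` relative to ``reference``.

    Positive dx means the frame's content sits further right than the
    reference.  Correct a frame with ``apply_shift(frame, -shift)``.

    On a periodic channel array the correlation peak repeats every channel
    interval; passing the previous frame's shift as ``center`` with a
    ``radius`` below half an interval exploits the continuity of stage
    drift to resolve that ambiguity.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if reference.shape != frame.shape:
        raise ValueError("reference and frame must have identical dimensions")
    cx, cy = (center.dx, center.dy) if center is not None else (0, 0)
    dx, deg_x = xcorr_argmax(
        mean_profile(reference, HORIZONTAL),
        mean_profile(frame, HORIZONTAL),
        return_degenerate=True,
        center=cx,
        radius=radius,
    )
    dy, deg_y = xcorr_argmax(
        mean_profile(reference, VERTICAL),
        mean_profile(frame, VERTICAL),
        return_degenerate=True,
        center=cy,
        radius=radius,
    )
    if deg_x or deg_y:
        log.warning("estimate_shift: structureless frame, returning (0, 0)")
    return ShiftVector(int(dx), int(dy))


def apply_shift(image: np.ndarray, shift: ShiftVector, fill=None) -> np.ndarray:
    """Translate ``image`` by (dx, dy); vacated pixels take the image median.

    Content moves by +dx columns and +dy rows, so a frame displaced by
    ``s = estimate_shift(ref, frame)`` is registered by
    ``apply_shift(frame, -s)``.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if abs(shift.dx) >= w or abs(shift.dy) >= h:
        raise ValueError("shift magnitude must be smaller than the image")
    if fill is None:
        fill = float(np.median(image))
    out = np.full_like(image, fill)
    dx, dy = shift.dx, shift.dy
    src_y = slice(max(0, -dy), h - max(0, dy))
    src_x = slice(max(0, -dx), w - max(0, dx))
    dst_y = slice(max(0, dy), h - max(0, -dy))
    dst_x = slice(max(0, dx), w - max(0, -dx))
    out[dst_y, dst_x] = image[src_y, src_x]
    return out


def estimate_rotation(
    image: np.ndarray,
    n_strips: int = 16,
    smooth_window: int = 9,
) -> RotationEstimate:
    """Estimate the rotation angle of the channel array from strip shifts.

    The image is sliced into ``n_strips`` vertical strips of width
    d = W // n_strips.  Positive theta means features shift towards larger y
    with increasing x; correct with ``rotate_image(image, -theta)``.

    Raises :class:`EstimationFailedError` when fewer than two strip shifts
    survive outlier rejection; callers fall back to theta = 0 with a warning.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if n_strips < 3:
        raise ValueError("need at least 3 strips")
    if w < 8 * n_strips:
        raise ValueError("strips would be narrower than 8 px")
    d = w // n_strips
    diffs = []
    for n in range(n_strips):
        strip = image[:, n * d : (n + 1) * d]
        v = mean_profile(strip, VERTICAL)
        vs = smooth(v, min(smooth_window, len(v)))
        diffs.append(np.diff(vs.values))
    # a strip-to-strip shift beyond tan(15 deg) * d would imply an
    # implausible chip rotation; bound the correlation search accordingly
    max_lag = max(2, int(np.ceil(np.tan(np.radians(MAX_PLAUSIBLE_ROTATION_DEG)) * d)))
    shifts = np.array(
        [
            xcorr_argmax_subpixel(diffs[n], diffs[n + 1], max_lag=max_lag)
            for n in range(n_strips - 1)
        ],
        dtype=float,
    )
    sigma = shifts.std()
    if sigma == 0:
        kept = np.ones(shifts.size, dtype=bool)
    else:
        kept = np.abs(np.median(shifts) - shifts) < 2.0 * sigma
    if kept.sum() < 2:
        raise EstimationFailedError("too few strip shifts survived outlier rejection")
    theta = float(np.arctan(shifts[kept].mean() / d))
    return RotationEstimate(theta, shifts, kept, float(d))


def rotate_image(image: np.ndarray, theta_rad: float, fill=None) -> np.ndarray:
    """Rotate about the image centre with bilinear interpolation.

    Positive theta moves features at larger x towards larger y (matching the
    sign of :func:`estimate_rotation`, whose output is undone by rotating by
    -theta).  Output dimensions are unchanged; out-of-frame pixels take the
    image median.  Angles beyond 15 degrees are physically implausible for a
    mounted chip and only produce a warning.
    """
    image = np.asarray(image, dtype=float)
    if abs(np.degrees(theta_rad)) > MAX_PLAUSIBLE_ROTATION_DEG:
        log.warning(
            "rotate_image: implausible angle %.2f deg", np.degrees(theta_rad)
        )
    if theta_rad == 0.0:
        return image.copy()
    if fill is None:
        fill = float(np.median(image))
    # scipy's positive angle moves features at larger x towards smaller y in
    # array coordinates; negate so our positive theta matches the estimator.
    return ndimage.rotate(
        image,
        angle=-np.degrees(theta_rad),
        reshape=False,
        order=1,
        mode="constant",
        cval=fill,
    )
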