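"""Cell detection inside a growth-channel crop.

Cells fill the channel width, so detection is one-dimensional: each cell is
a (top, bottom) interval of the channel's vertical mean-intensity profile.
The profile is cleaned by subtracting a heavily smoothed baseline (window
length = profile length) and smoothing again; local extrema found by a
sliding window yield cell candidates as pairs of adjacent maxima (cells are
dark, so a cell is the valley between two bright walls/gaps).  Candidates
pass three independent filters: a minimum physical length, a minimum
"blackness" (fraction of the candidate classified dark by Otsu binarization
of the crop), and a minimum "prominence" (gap between spline envelopes
through the cleaned profile's maxima and minima, evaluated at the candidate
centre).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateInputError
from .io_stack import Calibration
from .signal_core import VERTICAL, Profile, mean_profile, otsu_threshold, smooth

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Candidate filter thresholds and extrema-detector tunables.

    ``min_length_um`` rejects sub-cellular debris (default 1 um).
    ``blackness_threshold`` (default 0.5) is the minimum dark fraction for a
    true cell when ``dark_cells`` is set; flip ``dark_cells`` for inverted
    contrast.  ``prominence_min`` defaults to 2 % of the crop's intensity
    range when left ``None``.  ``extrema_min_delta_frac`` is the hysteresis
    of the sliding-window extrema detector: an adjacent maximum/minimum pair
    closer in value than this fraction of the cleaned profile's range is
    treated as noise and pruned.
    """

    min_length_um: float = 1.0
    blackness_threshold: float = 0.5
    dark_cells: bool = True
    prominence_min: float | None = None
    extrema_window_px: int = 5
    extrema_min_delta_frac: float = 0.05
    extrema_noise_mult: float = 8.0  # noise floor multiplier for the hysteresis
    smooth_window_px: int = 5

    def __post_init__(self) -> None:
        if self.min_length_um <= 0:
            raise ValueError("min_length_um must be positive")
        if not 0 < self.blackness_threshold < 1:
            raise ValueError("blackness_threshold must be in (0, 1)")
        if self.extrema_window_px < 3 or self.extrema_window_px % 2 == 0:
            raise ValueError("extrema_window_px must be odd and >= 3")


@dataclass
class CellCandidate:
    """A candidate cell as a half-open 1D interval within a channel crop."""

    top_px: int
    bottom_px: int
    length_um: float
    blackness: float = 0.0
    prominence: float = 0.0
    accepted: bool = False

    def __post_init__(self) -> None:
        if self.top_px >= self.bottom_px:
            raise ValueError("need top_px < bottom_px")

    @property
    def center_px(self) -> float:
        return 0.5 * (self.top_px + self.bottom_px)


def cleaned_profile(channel_crop: np.ndarray, smooth_window_px: int = 5) -> Profile:
    """Baseline-corrected, re-smoothed vertical profile of a channel crop.

    The baseline is the profile smoothed with a window as long as the
    profile itself, so slow illumination trends vanish while cell-scale
    structure survives.
    """
    crop = np.asarray(channel_crop, dtype=float)
    if crop.ndim != 2 or crop.shape[0] < 8:
        raise ValueError("channel crop must be 2D with height >= 8 px")
    v = mean_profile(crop, VERTICAL)
    baseline = smooth(v.values, v.values.size)
    cleaned = smooth(v.values - baseline, min(smooth_window_px, v.values.size))
    return Profile(cleaned, axis=VERTICAL)


def _window_extrema(values: np.ndarray, window: int, mode: str) -> list[int]:
    """Positions that are the maximum (or minimum) of their centred window.

    Plateaus of equal values collapse to their centre element.
    """
    n = values.size
    half = window // 2
    comp = values if mode == "max" else -values
    hits = []
    # windows are truncated at the boundaries: the profile ends of a channel
    # crop carry the bright margins that delimit the outermost cells, so
    # boundary extrema are kept deliberately
    for p in range(n):
        lo, hi = max(0, p - half), min(n, p + half + 1)
        if comp[p] >= comp[lo:hi].max():
            hits.append(p)
    # collapse plateau runs (consecutive hits with equal value) to the
    # centre, keeping only plateaus whose nearest differing neighbours are
    # consistent with the mode (a flat stretch on a slope is no extremum)
    out: list[int] = []
    i = 0
    while i < len(hits):
        j = i
        while (
            j + 1 < len(hits)
            and hits[j + 1] == hits[j] + 1
            and values[hits[j + 1]] == values[hits[i]]
        ):
            j += 1
        centre = hits[(i + j) // 2]
        level = comp[centre]
        left = centre
        while left > 0 and comp[left - 1] == level:
            left -= 1
        right = centre
        while right < n - 1 and comp[right + 1] == level:
            right += 1
        ok_left = left == 0 or comp[left - 1] < level
        ok_right = right == n - 1 or comp[right + 1] < level
        if ok_left and ok_right:
            out.append(centre)
        i = j + 1
    return out


def _enforce_alternation(
    values: np.ndarray, maxima: list[int], minima: list[int]
) -> tuple[list[int], list[int]]:
    """Merge runs of same-type extrema so maxima and minima alternate."""
    events = sorted([(p, "max") for p in maxima] + [(p, "min") for p in minima])
    merged: list[tuple[int, str]] = []
    for pos, kind in events:
        if merged and merged[-1][1] == kind:
            prev, _ = merged[-1]
            better = (
                pos
                if (values[pos] > values[prev]) == (kind == "max")
                and values[pos] != values[prev]
                else prev
            )
            merged[-1] = (better, kind)
        else:
            merged.append((pos, kind))
    return (
        [p for p, k in merged if k == "max"],
        [p for p, k in merged if k == "min"],
    )


def _prune_shallow(
    values: np.ndarray,
    maxima: list[int],
    minima: list[int],
    min_delta: float,
) -> tuple[list[int], list[int]]:
    """Drop shallow adjacent max/min pairs on the dark side of the profile.

    This is the hysteresis of the sliding-window detector: noise wiggles
    inside a dark cell produce extrema pairs of tiny amplitude which would
    otherwise split the cell in two.  Pruning is restricted to pairs sitting
    below the profile's midrange: bright-side wiggles cannot split a cell
    (their candidates fail the blackness filter), while the structural
    maxima delimiting cells in bright regions must survive regardless of
    their local amplitude.
    """
    events = sorted([(p, "max") for p in maxima] + [(p, "min") for p in minima])
    midrange = 0.5 * (values.max() + values.min())
    changed = True
    while changed and len(events) > 1:
        changed = False
        gaps = []
        for i in range(len(events) - 1):
            v1, v2 = values[events[i][0]], values[events[i + 1][0]]
            if max(v1, v2) < midrange:
                gaps.append(abs(v2 - v1))
            else:
                gaps.append(np.inf)
        i = int(np.argmin(gaps))
        if gaps[i] < min_delta:
            del events[i : i + 2]
            events_vals = values
            # re-merge neighbours of the removed pair if same type
            merged: list[tuple[int, str]] = []
            for pos, kind in events:
                if merged and merged[-1][1] == kind:
                    prev, _ = merged[-1]
                    keep = (
                        pos
                        if (events_vals[pos] > events_vals[prev]) == (kind == "max")
                        else prev
                    )
                    merged[-1] = (keep, kind)
                else:
                    merged.append((pos, kind))
            events = merged
            changed = True
    return (
        [p for p, k in events if k == "max"],
        [p for p, k in events if k == "min"],
    )


def find_extrema(
    profile,
    window: int = 5,
    min_delta: float = 0.0,
) -> tuple[list[int], list[int]]:
    """Alternating local maxima and minima via a sliding-window scan.

    ``min_delta`` is an absolute amplitude hysteresis; pairs of adjacent
    extrema differing by less are pruned as noise.
    """
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    maxima = _window_extrema(values, window, "max")
    minima = _window_extrema(values, window, "min")
    maxima, minima = _enforce_alternation(values, maxima, minima)
    if min_delta > 0:
        maxima, minima = _prune_shallow(values, maxima, minima, min_delta)
    return maxima, minima


def candidates_from_extrema(
    maxima: list[int], pixel_size_um: float
) -> list[CellCandidate]:
    """One candidate per pair of adjacent profile maxima, top to bottom."""
    out = []
    for top, bottom in zip(maxima, maxima[1:]):
        out.append(
            CellCandidate(
                top_px=int(top),
                bottom_px=int(bottom),
                length_um=(bottom - top) * pixel_size_um,
            )
        )
    return out


def score_blackness(
    candidate: CellCandidate, channel_crop: np.ndarray, dark_cells: bool = True
) -> float:
    """Fraction of the candidate's extent classified dark by Otsu binarization.

    The crop is binarized (dark class = 1 when ``dark_cells``); the vertical
    mean profile of the binary image is averaged over [top, bottom).  A crop
    too flat for Otsu scores 0 with a warning.
    """
    crop = np.asarray(channel_crop, dtype=float)
    try:
        thr = otsu_threshold(crop)
    except DegenerateInputError:
        log.warning("score_blackness: degenerate crop, blackness = 0")
        return 0.0
    binary = (crop <= thr) if dark_cells else (crop > thr)
    prof = binary.astype(float).mean(axis=1)
    return float(prof[candidate.top_px : candidate.bottom_px].mean())


def _envelope(points_x: list[int], points_y: np.ndarray):
    """Interpolant through extrema: shape-preserving cubic for >= 4 points.

    A monotone (PCHIP) cubic is used instead of a natural cubic spline:
    envelope nodes are irregularly spaced and a natural spline's overshoot
    between a bright and a dark node can push the upper envelope below the
    lower one, faking zero prominence for a perfectly good cell.
    """
    if len(points_x) == 0:
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    if len(points_x) == 1:
        y = float(points_y[0])
        return lambda x: np.full_like(np.asarray(x, dtype=float), y)
    xs = np.asarray(points_x, dtype=float)
    ys = np.asarray(points_y, dtype=float)
    if len(points_x) >= 4:
        spline = PchipInterpolator(xs, ys, extrapolate=True)
        return lambda x: np.asarray(spline(x), dtype=float)
    return lambda x: np.interp(np.asarray(x, dtype=float), xs, ys)


def score_prominence(
    candidate: CellCandidate,
    cleaned,
    maxima: list[int],
    minima: list[int],
) -> float:
    """Upper-minus-lower envelope gap at the candidate centre.

    The upper envelope interpolates the cleaned profile's maxima, the lower
    one its minima; a deep cell dip separates the envelopes while jitter on
    a flat stretch does not.
    """
    values = cleaned.values if isinstance(cleaned, Profile) else np.asarray(cleaned)
    upper = _envelope(maxima, values[np.asarray(maxima, dtype=int)] if maxima else values[:0])
    lower = _envelope(minima, values[np.asarray(minima, dtype=int)] if minima else values[:0])
    c = candidate.center_px
    return float(max(0.0, upper(c) - lower(c)))


def detect_cells(
    channel_crop: np.ndarray,
    params: DetectionParams,
    calibration: Calibration,
) -> list[CellCandidate]:
    """Detect the accepted cells of one channel crop, ordered top to bottom.

    Candidates must be at least ``min_length_um`` long, at least 50 % dark
    under Otsu binarization (polarity configurable), and prominent enough to
    stand out of the cleaned profile's noise floor.
    """
    crop = np.asarray(channel_crop, dtype=float)
    if crop.ndim != 2 or crop.shape[0] < 8:
        return []
    cleaned = cleaned_profile(crop, params.smooth_window_px)
    crange = float(np.ptp(cleaned.values))
    if crange == 0:
        return []
    # hysteresis: at least a fraction of the profile range, and comfortably
    # above the noise floor estimated from robust first differences
    noise = 1.4826 * float(np.median(np.abs(np.diff(cleaned.values)))) / np.sqrt(2)
    min_delta = max(
        params.extrema_min_delta_frac * crange,
        params.extrema_noise_mult * noise,
    )
    maxima, minima = find_extrema(
        cleaned,
        window=params.extrema_window_px,
        min_delta=min_delta,
    )
    candidates = candidates_from_extrema(maxima, calibration.pixel_size_um)
    prom_min = params.prominence_min
    if prom_min is None:
        prom_min = 0.02 * float(np.ptp(crop))
    accepted = []
    for cand in candidates:
        cand.blackness = score_blackness(cand, crop, dark_cells=params.dark_cells)
        cand.prominence = score_prominence(cand, cleaned, maxima, minima)
        cand.accepted = (
            cand.length_um >= params.min_length_um
            and cand.blackness >= params.blackness_threshold
            and cand.prominence >= prom_min
        )
        if cand.accepted:
            accepted.append(cand)
    return accepted
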