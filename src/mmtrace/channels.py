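"""Channel-array and growth-channel detection.

The mother-machine array is periodic, so it is found in the frequency
domain: the dominant period i_C of the horizontal mean-intensity profile
gives the channel spacing, and the array's vertical extent is the largest
run of horizontal strips whose own dominant period matches the global one
(the spectral approach acts as a bandpass filter, making it robust to uneven
illumination).  Channels appear brighter than the surrounding device
material, so the derivative h' of the horizontal profile peaks positive at
each channel's left wall and negative at its right wall.  Splitting h' into
the left/right edge signals c_l and c_r and cross-correlating them yields
the channel width w_C; correlating a synthetic binary comb a(x) (ones at
multiples of i_C and at w_C past them) against c_l + c_r yields the phase
phi.  The comb shifted by phi weights the edge signal into the robustified
channel signal h_tau, whose per-tooth mass separates true channels from
channel-free border regions by thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    GeometryError,
    MMTraceError,
    StructureNotFoundError,
)
from .signal_core import (
    HORIZONTAL,
    Profile,
    band_power_fraction,
    dominant_frequency,
    mean_profile,
    refine_period_autocorr,
    smooth,
    spectral_peak_fraction,
    xcorr_argmax,
)

log = logging.getLogger(__name__)


@dataclass
class ChannelDetectionParams:
    """Tunables of the array/channel localisation stage."""

    strip_height_px: int = 16
    period_tolerance: float = 0.2  # relative match of strip vs global period
    min_peak_fraction: float = 0.05  # spectral power share needed for "structure"
    band_fraction: float = 0.1  # power share at the channel frequency (frame check)
    strip_rho: float = 0.2  # wall-edge autocorrelation ratio per strip
    threshold_fraction: float = 0.4  # of the upper-quartile per-tooth h_tau mass
    profile_smooth_px: int = 5


@dataclass
class ChannelGeometry:
    """Detected array extent and per-channel crop boxes (half-open pixels)."""

    array_top: int
    array_bottom: int
    interval_px: float
    width_px: int
    phase_px: float
    channel_boxes: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.array_top < self.array_bottom:
            raise ValueError("need 0 <= array_top < array_bottom")
        if not 2 <= self.width_px < self.interval_px:
            raise ValueError("need 2 <= width_px < interval_px")
        xs = [b[0] for b in self.channel_boxes]
        if xs != sorted(xs):
            raise ValueError("channel boxes must be sorted by x_left")
        for left, right in self.channel_boxes:
            if abs((right - left) - self.width_px) > 1:
                raise ValueError("box width must equal width_px within 1 px")

    @property
    def n_channels(self) -> int:
        return len(self.channel_boxes)


def _edge_autocorr_ratio(values: np.ndarray, lag: int) -> float:
    """Autocorrelation of the edge train |h'| at ``lag``, relative to lag 0.

    Channel walls repeat at the channel interval in every row band of the
    array no matter how cells fill the channels, so this ratio is high for
    array strips and near zero for structure-free rows.
    """
    e = np.abs(np.diff(values))
    e = e - e.mean()
    c = np.correlate(e, e, mode="full")[e.size - 1 :]
    if c[0] <= 0 or lag >= e.size:
        return 0.0
    lo, hi = max(1, lag - 2), min(e.size - 1, lag + 2)
    return float(c[lo : hi + 1].max() / c[0])


def find_vertical_extent(
    image: np.ndarray,
    strip_height_px: int = 16,
    period_tolerance: float = 0.2,
    min_peak_fraction: float = 0.05,
    strip_rho: float = 0.2,
    smooth_px: int = 5,
    period_hint: float | None = None,
) -> tuple[int, int]:
    """Vertical extent [top, bottom) of the channel array.

    Returns the largest run of consecutive horizontal strips that share the
    whole image's channel periodicity: a strip matches when its dominant
    period is (a harmonic of) the global period within ``period_tolerance``,
    or when its wall-edge train repeats at the global interval with
    autocorrelation ratio at least ``strip_rho``.  Boundaries snap to strip
    edges.  Raises :class:`StructureNotFoundError` when the image as a whole
    has no significant spectral peak or no strip matches.
    """
    image = np.asarray(image, dtype=float)
    # the structure check runs on the raw profile: smoothing low-passes
    # noise and would fake a spectral peak on a structure-free frame
    if spectral_peak_fraction(mean_profile(image, HORIZONTAL)) < min_peak_fraction:
        raise StructureNotFoundError("no periodic structure in the frame")
    h_img = smooth(mean_profile(image, HORIZONTAL), smooth_px)
    if period_hint is not None:
        global_period = float(period_hint)
    else:
        try:
            global_period = estimate_interval(h_img)
        except DegenerateInputError as exc:
            raise StructureNotFoundError(str(exc)) from exc

    height = image.shape[0]
    n_strips = max(1, height // strip_height_px)
    matches = np.zeros(n_strips, dtype=bool)
    for i in range(n_strips):
        top = i * strip_height_px
        bottom = height if i == n_strips - 1 else (i + 1) * strip_height_px
        strip = image[top:bottom]
        prof = smooth(mean_profile(strip, HORIZONTAL), smooth_px)
        if spectral_peak_fraction(prof) < min_peak_fraction:
            continue
        try:
            period, _ = dominant_frequency(prof)
        except DegenerateInputError:
            continue
        # cells can shift a strip's dominant peak onto a harmonic (walls
        # repeat within each period) or a subharmonic (cell columns ending
        # at that row in alternating channels), so dominant-period equality
        # alone is brittle; a strip also matches when its wall-edge train
        # repeats at the global interval (the bandpass view of the same
        # criterion, insensitive to how cells fill the channels)
        harmonic = any(
            abs(k * period - global_period) <= period_tolerance * global_period
            for k in (1, 2, 3, 4)
        )
        walls = (
            _edge_autocorr_ratio(prof.values, int(round(global_period)))
            >= strip_rho
        )
        matches[i] = harmonic or walls
    # one or two ambiguous strips (rows where cell columns end in several
    # channels at once) must not split the array in two
    for gap in (1, 2):
        for i in range(1, n_strips - gap):
            if matches[i - 1] and matches[i + gap]:
                matches[i : i + gap] = True
    if not matches.any():
        raise StructureNotFoundError("no strip matches the global channel period")

    best_len = best_start = 0
    start = None
    for i, m in enumerate(matches):
        if m and start is None:
            start = i
        if (not m or i == n_strips - 1) and start is not None:
            end = i + 1 if m else i
            if end - start > best_len:
                best_len, best_start = end - start, start
            start = None
    top = best_start * strip_height_px
    bottom = min(height, (best_start + best_len) * strip_height_px)
    if best_start + best_len == n_strips:
        bottom = height
    return top, bottom


def estimate_interval(h) -> float:
    """Channel spacing i_C from the dominant period, harmonic-disambiguated.

    When channels are dense with cells, the strongest spectral peak can sit
    on a harmonic of the true spacing (the wall pattern repeats within each
    period).  The spacing is therefore taken from the overlap-normalised
    autocorrelation instead: among its local maxima, the smallest lag
    scoring at least 80 % of the best peak is the fundamental — the true
    period aligns the whole pattern, a harmonic only part of it.  The FFT
    estimate remains the fallback for profiles too short for a peak search.
    """
    values = h.values if isinstance(h, Profile) else np.asarray(h, dtype=float)
    p0, _ = dominant_frequency(values)
    # two complementary views of the periodicity: the raw profile (bright
    # lumen vs darker device; immune to edge-train ambiguities near 50 %
    # duty cycle) and the wall-edge spike train |h'| (immune to the margin
    # and illumination biases of the raw profile)
    edges = np.abs(np.diff(values))

    def _norm_autocorr(x: np.ndarray) -> np.ndarray:
        xm = x - x.mean()
        c = np.correlate(xm, xm, mode="full")[xm.size - 1 :]
        return c / np.maximum(np.arange(xm.size, 0, -1), 1)

    nh = _norm_autocorr(values)
    ne = _norm_autocorr(edges)
    n = min(nh.size, ne.size)
    lo, hi = 4, n // 3
    if hi <= lo:
        return float(p0)
    band = slice(lo, hi + 1)
    scale_h = np.abs(nh[band]).max() or 1.0
    scale_e = np.abs(ne[band]).max() or 1.0
    combined = nh[:n] / scale_h + ne[:n] / scale_e
    window = combined[band]
    interior = (window >= np.roll(window, 1)) & (window >= np.roll(window, -1))
    interior[0] = interior[-1] = False
    peaks = np.flatnonzero(interior) + lo
    peaks = peaks[combined[peaks] > 0]
    if peaks.size == 0:
        return float(p0)
    best = combined[peaks].max()
    lag = int(peaks[np.argmax(combined[peaks] >= 0.8 * best)])
    return refine_period_autocorr(edges, float(lag))


def edge_signals(h) -> tuple[np.ndarray, np.ndarray]:
    """Left/right channel-wall signals from the horizontal profile.

    h' is taken by forward differences (zero-padded back to full length);
    c_l keeps the positive part (left walls, intensity rising into the
    channel), c_r the absolute negative part (right walls).
    """
    values = h.values if isinstance(h, Profile) else np.asarray(h, dtype=float)
    hp = np.append(np.diff(values), 0.0)
    c_l = 0.5 * (np.abs(hp) + hp)
    c_r = 0.5 * (np.abs(hp) - hp)
    return c_l, c_r


def channel_width_candidates(h, interval_px: float, max_candidates: int = 3) -> list[int]:
    """Plausible channel widths: top local maxima of the c_l/c_r correlation.

    The best lag is occasionally ambiguous (gaps between channels can
    mimic channels when the duty cycle is near one half); callers may score
    the candidates by the brightness of the boxes they produce.
    """
    c_l, c_r = edge_signals(h)
    if not c_l.any() or not c_r.any():
        raise GeometryError("flat profile: no channel edges")
    lags = np.arange(1, max(2, int(np.ceil(interval_px))))
    lags = lags[lags < c_l.size]
    scores = np.array([float(np.dot(c_l[: c_l.size - l], c_r[l:])) for l in lags])
    if not scores.any():
        raise GeometryError("no edge correlation in (0, interval)")
    is_peak = np.ones(scores.size, dtype=bool)
    is_peak[1:] &= scores[1:] >= scores[:-1]
    is_peak[:-1] &= scores[:-1] >= scores[1:]
    peaks = np.flatnonzero(is_peak & (scores > 0.2 * scores.max()))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(scores))])
    order = peaks[np.argsort(scores[peaks])[::-1]][:max_candidates]
    return [int(lags[i]) for i in order]


def channel_width(h, interval_px: float) -> int:
    """Channel width w_C as the lag of peak correlation between c_l and c_r.

    A channel's right wall sits between 0 and i_C past its left wall by
    construction, so the correlation peak is searched over that lag range
    only (wall shadows would otherwise offer spurious negative-lag pairings).
    """
    c_l, c_r = edge_signals(h)
    if not c_l.any() or not c_r.any():
        raise GeometryError("flat profile: no channel edges")
    lags = np.arange(1, max(2, int(np.ceil(interval_px))))
    lags = lags[lags < c_l.size]
    scores = np.array(
        [float(np.dot(c_l[: c_l.size - l], c_r[l:])) for l in lags]
    )
    if not scores.any():
        raise GeometryError("no edge correlation in (0, interval)")
    w = int(lags[int(np.argmax(scores))])
    if not 0 < w < interval_px:
        raise GeometryError(f"channel width {w} outside (0, {interval_px:.1f})")
    return w


def build_reference_signal(
    interval_px: float, width_px: int, length: int
) -> Profile:
    """Binary comb with ones at both walls of each nominal channel.

    Ones sit at round(m * i_C) and round(m * i_C + w_C) for every repeat m
    that fits; rounding each tooth independently distributes the remainder
    of a non-integer interval instead of accumulating it.
    """
    if not 0 < width_px < interval_px <= length:
        raise ValueError("need 0 < width_px < interval_px <= length")
    a = np.zeros(length)
    m = 0
    while True:
        left = int(round(m * interval_px))
        if left >= length:
            break
        a[left] = 1.0
        right = int(round(m * interval_px + width_px))
        if right < length:
            a[right] = 1.0
        m += 1
    return Profile(a, axis=HORIZONTAL)


def estimate_phase(a, edges, interval_px: float) -> float:
    """Phase phi in [0, i_C): shift of the observed walls vs the reference comb."""
    edges_v = edges.values if isinstance(edges, Profile) else np.asarray(edges)
    if not np.asarray(edges_v).any():
        raise GeometryError("degenerate edge signal")
    phi = xcorr_argmax(a, edges)
    return float(phi % interval_px)


def robust_channel_signal(a, phase_px: float, c_l, c_r) -> np.ndarray:
    """h_tau: the comb shifted by phi, applied as a weight to c_l + c_r.

    The comb teeth are widened by one pixel on each side before the
    element-wise product so that the rounding of a non-integer interval
    cannot drop a genuine wall; h_tau stays zero away from comb teeth.
    """
    av = a.values if isinstance(a, Profile) else np.asarray(a, dtype=float)
    c_lv = np.asarray(c_l, dtype=float)
    c_rv = np.asarray(c_r, dtype=float)
    if not av.size == c_lv.size == c_rv.size:
        raise ValueError("incompatible signal lengths")
    shift = int(round(phase_px))
    shifted = np.zeros_like(av)
    if shift < av.size:
        shifted[shift:] = av[: av.size - shift]
    widened = shifted.copy()
    for offset in (-2, -1, 1, 2):
        moved = np.zeros_like(shifted)
        if offset > 0:
            moved[offset:] = shifted[:-offset]
        else:
            moved[:offset] = shifted[-offset:]
        widened = np.maximum(widened, moved)
    return widened * (c_lv + c_rv)


def extract_channels(
    image: np.ndarray,
    array_top: int,
    array_bottom: int,
    interval_px: float,
    width_px: int,
    phase_px: float,
    h_tau: np.ndarray,
    threshold_fraction: float = 0.4,
) -> ChannelGeometry:
    """Turn comb positions with sufficient h_tau support into channel boxes.

    A comb position qualifies when the h_tau mass around its two walls
    exceeds ``threshold_fraction`` of the upper-quartile per-tooth mass
    (robust against both channel-free border teeth and individual weak
    channels), which rejects the channel-free border regions.  Raises
    :class:`StructureNotFoundError` when nothing qualifies.
    """
    w = image.shape[1]
    positions = []
    m = 0
    while True:
        left = int(round(m * interval_px + phase_px))
        if left + width_px > w:
            break
        if left >= 0:
            positions.append(left)
        m += 1
    if not positions:
        raise StructureNotFoundError("no comb position fits in the frame")
    masses = np.array(
        [
            h_tau[max(0, x - 3) : min(w, x + width_px + 4)].sum()
            for x in positions
        ]
    )
    if masses.sum() <= 0:
        raise StructureNotFoundError("h_tau carries no mass at comb positions")
    keep = masses >= threshold_fraction * np.percentile(masses, 75)
    boxes = [(x, x + width_px) for x, k in zip(positions, keep) if k]
    if not boxes:
        raise StructureNotFoundError("no channel exceeded the h_tau threshold")
    return ChannelGeometry(
        array_top=array_top,
        array_bottom=array_bottom,
        interval_px=interval_px,
        width_px=width_px,
        phase_px=phase_px,
        channel_boxes=boxes,
    )


def detect_geometry(
    image: np.ndarray, params: ChannelDetectionParams | None = None
) -> ChannelGeometry:
    """Full geometry detection for one registered, orientation-corrected frame.

    Runs two passes: the first pass estimates the channel interval from the
    whole image, which can be thrown off by dense cell rows when locating
    the array's vertical extent; the second pass repeats the extent search
    with the first pass's fitted interval as the periodicity reference and
    keeps its result when it succeeds.
    """
    params = params or ChannelDetectionParams()
    image = np.asarray(image, dtype=float)
    first = _detect_geometry_once(image, params, period_hint=None)
    try:
        second = _detect_geometry_once(
            image, params, period_hint=first.interval_px
        )
    except MMTraceError:
        return first
    # the refinement exists to recover an extent truncated by a bad global
    # period; adopt it only when it actually enlarges the array
    if (second.array_bottom - second.array_top) > (
        first.array_bottom - first.array_top
    ):
        return second
    return first


def _detect_geometry_once(
    image: np.ndarray,
    params: ChannelDetectionParams,
    period_hint: float | None,
) -> ChannelGeometry:
    top, bottom = find_vertical_extent(
        image,
        period_hint=period_hint,
        strip_height_px=params.strip_height_px,
        period_tolerance=params.period_tolerance,
        min_peak_fraction=params.min_peak_fraction,
        strip_rho=params.strip_rho,
        smooth_px=params.profile_smooth_px,
    )
    structure = image[top:bottom]
    h = smooth(mean_profile(structure, HORIZONTAL), params.profile_smooth_px)
    interval_px = estimate_interval(h)
    # the interval estimate can land on half or double the true spacing in
    # degenerate duty cycles; fit all three and decide by how informatively
    # each comb explains the wall-edge mass: a layout must capture most of
    # the mass (a doubled period misses every other channel) without having
    # to cover nearly everything to do so (a halved period covers all)
    fits = []
    for factor in (0.5, 1.0, 2.0):
        period = interval_px * factor
        if not 4 <= period <= len(h) / 3:
            continue
        fit = _fit_geometry(image, top, bottom, period, h, params)
        if fit is not None:
            fits.append((period,) + fit)  # (period, geom, capture, coverage, contrast)
    if not fits:
        raise StructureNotFoundError("no channel configuration fits the frame")
    informative = [f for f in fits if f[3] <= 0.85]
    if informative:
        captured = [f for f in informative if f[2] >= 0.75]
        chosen = min(captured, key=lambda f: f[0]) if captured else max(
            informative, key=lambda f: f[2]
        )
    else:
        chosen = max(fits, key=lambda f: f[4])
    return chosen[1]


def _fit_geometry(
    image: np.ndarray,
    top: int,
    bottom: int,
    interval_px: float,
    h: Profile,
    params: ChannelDetectionParams,
) -> tuple[ChannelGeometry, float, float, float] | None:
    """Best box layout for one interval estimate, plus its edge-mass capture.

    The correlation lag fixes the channel width; only the comb phase has a
    rare ambiguity (near 50 % duty cycle the comb can lock onto the gaps
    instead of the channels, shifted by one width).  The three phase
    variants are compared by the contrast between box interiors and their
    immediate flanks: a true channel is brighter than the dark wall ridges
    flanking it whatever its cell load, while a gap-locked comb flanks its
    boxes with channel edges instead.
    """
    c_l, c_r = edge_signals(h)
    hv = h.values
    edge_sum = c_l + c_r
    total_edge = float(edge_sum.sum())
    if total_edge <= 0:
        return None
    try:
        width_candidates = channel_width_candidates(h, interval_px)
    except GeometryError:
        return None

    def flank_contrast(geom: ChannelGeometry) -> float:
        inside = []
        flanks = []
        for left, right in geom.channel_boxes:
            inside.append(hv[left:right])
            flanks.append(hv[max(0, left - 2) : left])
            flanks.append(hv[right : min(hv.size, right + 2)])
        flank_list = [f for f in flanks if f.size]
        if not inside or not flank_list:
            return 0.0
        return float(np.concatenate(inside).mean() - np.concatenate(flank_list).mean())

    def capture_and_coverage(geom: ChannelGeometry) -> tuple[float, float]:
        # fraction of the wall-edge mass inside the comb windows, and the
        # fraction of the profile those windows occupy
        tooth = np.zeros(edge_sum.size, dtype=bool)
        m = 0
        while True:
            x0 = int(round(m * geom.interval_px + geom.phase_px))
            if x0 >= edge_sum.size:
                break
            lo = max(0, x0 - 2)
            hi = min(edge_sum.size, x0 + geom.width_px + 3)
            tooth[lo:hi] = True
            m += 1
        return float(edge_sum[tooth].sum()) / total_edge, float(tooth.mean())

    for width_px in width_candidates:
        if not 0 < width_px < interval_px:
            continue
        a = build_reference_signal(interval_px, width_px, len(h))
        try:
            phase0 = estimate_phase(a, c_l + c_r, interval_px)
        except GeometryError:
            continue
        phases = {round(phase0 % interval_px, 3)}
        for alt in (phase0 + width_px, phase0 - width_px):
            phases.add(round(alt % interval_px, 3))
        best: tuple[float, ChannelGeometry] | None = None
        for phase in phases:
            h_tau = robust_channel_signal(a, phase, c_l, c_r)
            try:
                geom = extract_channels(
                    image,
                    top,
                    bottom,
                    interval_px,
                    width_px,
                    phase,
                    h_tau,
                    threshold_fraction=params.threshold_fraction,
                )
            except (StructureNotFoundError, ValueError):
                continue
            contrast = flank_contrast(geom)
            if best is None or contrast > best[0]:
                best = (contrast, geom)
        if best is not None:
            cap, cov = capture_and_coverage(best[1])
            return best[1], cap, cov, best[0]
    return None


def detect_frame_boxes(
    image: np.ndarray,
    canonical: ChannelGeometry,
    params: ChannelDetectionParams | None = None,
) -> ChannelGeometry:
    """Re-locate the channel boxes of one frame given the canonical geometry.

    The array rows, channel interval and width are physical constants of the
    chip, so only the phase (the residual sub-interval shift left after
    integer-pixel registration) is re-estimated per frame; the comb and
    h_tau thresholding then yield this frame's boxes.  Raises
    :class:`StructureNotFoundError` when the frame shows no channel
    periodicity at all.
    """
    params = params or ChannelDetectionParams()
    image = np.asarray(image, dtype=float)
    structure = image[canonical.array_top : canonical.array_bottom]
    h = smooth(mean_profile(structure, HORIZONTAL), params.profile_smooth_px)
    if (
        band_power_fraction(h, canonical.interval_px)
        + band_power_fraction(h, canonical.interval_px / 2)
    ) < params.band_fraction:
        raise StructureNotFoundError("frame carries no channel periodicity")
    c_l, c_r = edge_signals(h)
    a = build_reference_signal(
        canonical.interval_px, canonical.width_px, len(h)
    )
    phase = estimate_phase(a, c_l + c_r, canonical.interval_px)
    h_tau = robust_channel_signal(a, phase, c_l, c_r)
    return extract_channels(
        image,
        canonical.array_top,
        canonical.array_bottom,
        canonical.interval_px,
        canonical.width_px,
        phase,
        h_tau,
        threshold_fraction=params.threshold_fraction,
    )


def crop_channels(
    image: np.ndarray, geometry: ChannelGeometry
) -> list[np.ndarray]:
    """Per-channel sub-images [array_top, array_bottom) x [x_left, x_right)."""
    return [
        np.asarray(image, dtype=float)[
            geometry.array_top : geometry.array_bottom, left:right
        ]
        for left, right in geometry.channel_boxes
    ]


def match_channels(
    boxes: list[tuple[int, int]],
    reference_boxes: list[tuple[int, int]],
    interval_px: float,
) -> dict[int, int]:
    """Match per-frame boxes to canonical reference boxes by nearest x_left.

    Gives each growth channel a stable identity across frames.  A detected
    box maps to the nearest reference box within i_C / 2; unmatched boxes are
    dropped (they are border artifacts of a single frame).
    """
    mapping: dict[int, int] = {}
    ref_x = np.array([b[0] for b in reference_boxes], dtype=float)
    taken: set[int] = set()
    for i, (left, _right) in enumerate(boxes):
        j = int(np.argmin(np.abs(ref_x - left)))
        if abs(ref_x[j] - left) <= interval_px / 2 and j not in taken:
            mapping[i] = j
            taken.add(j)
    return mapping
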