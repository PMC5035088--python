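"""Shared 1D signal primitives.

Everything downstream of raw pixels runs on mean-intensity profiles: the
horizontal profile ``h(x)`` averages a ``W x H`` image over rows, the vertical
profile ``v(y)`` averages over columns.  Registration, orientation correction,
channel localisation and cell detection are all built from four operations on
such profiles: Hamming-window smoothing, cross-correlation argmax, dominant
spectral period estimation, and Otsu thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError

log = logging.getLogger(__name__)

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


@dataclass
class Profile:
    """A 1D mean-intensity profile.

    Parameters
    ----------
    values:
        Finite real sequence, length >= 2.
    axis:
        ``"horizontal"`` (indexed by image column x) or ``"vertical"``
        (indexed by image row y).
    origin:
        Pixel offset of element 0 in the source image, so profiles of crops
        can be mapped back to full-frame coordinates.
    """

    values: np.ndarray
    axis: str = HORIZONTAL
    origin: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("profile must be 1D with length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def __len__(self) -> int:
        return self.values.size


def _as_values(profile) -> np.ndarray:
    if isinstance(profile, Profile):
        return profile.values
    return np.asarray(profile, dtype=float)


def mean_profile(image: np.ndarray, axis: str) -> Profile:
    """Mean-intensity profile of ``image`` along one axis.

    ``image`` is indexed ``[y, x]``.  The horizontal profile has one element
    per column (mean over y, length W); the vertical profile one element per
    row (mean over x, length H).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if axis == HORIZONTAL:
        return Profile(image.mean(axis=0), axis=HORIZONTAL)
    if axis == VERTICAL:
        return Profile(image.mean(axis=1), axis=VERTICAL)
    raise ValueError(f"unknown axis {axis!r}")


def hamming_kernel(window_len: int) -> np.ndarray:
    """Unit-sum Hamming window of ``window_len`` taps."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len == 1:
        return np.ones(1)
    w = np.hamming(window_len)
    return w / w.sum()


def smooth(profile, window_len: int):
    """Convolve with a unit-sum Hamming window; reflected boundaries.

    Output length equals input length.  ``window_len == 1`` is the identity;
    a window spanning the whole profile yields the heavily smoothed baseline
    used in cell detection.
    """
    values = _as_values(profile)
    if not 1 <= window_len <= values.size:
        raise ValueError("window_len must satisfy 1 <= window_len <= len(profile)")
    out = ndimage.convolve1d(values, hamming_kernel(window_len), mode="reflect")
    if isinstance(profile, Profile):
        return replace(profile, values=out)
    return out


def xcorr_argmax(
    a,
    b,
    return_degenerate: bool = False,
    center: int = 0,
    radius: int | None = None,
):
    """Lag of the peak of the linear cross-correlation of ``a`` against ``b``.

    Both signals are mean-subtracted first.  The sign convention is that a
    positive shift means ``b`` is displaced in +x relative to ``a``, i.e. if
    ``b(x) = a(x - k)`` the function returns ``k``.  Ties are broken towards
    the smallest-magnitude lag; a structure-free (flat) input is degenerate
    and yields lag 0 plus a warning.  When ``radius`` is given the search is
    restricted to |lag - center| <= radius (used when a physical bound on
    the shift is known, e.g. continuous stage drift).
    """
    av = _as_values(a)
    bv = _as_values(b)
    if av.size != bv.size:
        raise ValueError("signals must have equal length")
    if av.size < 2:
        raise ValueError("signals must have length >= 2")
    am = av - av.mean()
    bm = bv - bv.mean()
    if not am.any() or not bm.any():
        log.warning("xcorr_argmax: flat signal, returning lag 0")
        return (0, True) if return_degenerate else 0
    corr = signal.correlate(bm, am, mode="full", method="auto")
    lags = signal.correlation_lags(bm.size, am.size, mode="full")
    if radius is not None:
        inside = np.abs(lags - center) <= radius
        if inside.any():
            corr = np.where(inside, corr, -np.inf)
    peak = corr.max()
    # all lags within numerical noise of the peak tie; keep smallest |lag|
    ties = lags[corr >= peak - 1e-9 * max(abs(peak), 1.0)]
    order = np.lexsort((ties, np.abs(ties)))
    best = int(ties[order[0]])
    return (best, False) if return_degenerate else best


def xcorr_argmax_subpixel(a, b, max_lag: int | None = None) -> float:
    """Like :func:`xcorr_argmax` but refined to sub-pixel precision.

    The integer peak lag is refined by parabolic interpolation over the
    3-sample neighbourhood of the correlation peak.  ``max_lag`` restricts
    the search to |lag| <= max_lag (used when a physical bound on the shift
    is known).  Used where fractional shifts matter (strip shifts feeding
    the rotation angle); plain frame registration stays integer-pixel.
    """
    av = _as_values(a)
    bv = _as_values(b)
    if av.size != bv.size:
        raise ValueError("signals must have equal length")
    am = av - av.mean()
    bm = bv - bv.mean()
    if not am.any() or not bm.any():
        log.warning("xcorr_argmax_subpixel: flat signal, returning 0.0")
        return 0.0
    corr = signal.correlate(bm, am, mode="full", method="auto")
    lags = signal.correlation_lags(bm.size, am.size, mode="full")
    if max_lag is not None:
        corr = np.where(np.abs(lags) <= max_lag, corr, -np.inf)
    i = int(np.argmax(corr))
    delta = 0.0
    if 0 < i < corr.size - 1:
        c0, c1, c2 = corr[i - 1], corr[i], corr[i + 1]
        denom = c0 - 2 * c1 + c2
        if np.isfinite(denom) and denom != 0:
            delta = float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    return float(lags[i] + delta)


def dominant_frequency(profile, min_period: float = 2.0) -> tuple[float, float]:
    """Period (px) and power of the strongest non-DC spectral peak.

    The profile is mean-subtracted; periods longer than half the profile are
    excluded (they are indistinguishable from slow illumination trends).  The
    peak bin is refined by parabolic interpolation over its 3-bin
    neighbourhood, giving sub-bin period resolution.
    """
    values = _as_values(profile)
    n = values.size
    if n < 8:
        raise ValueError("profile too short for spectral analysis (need >= 8)")
    x = values - values.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    if not power[1:].any():
        raise DegenerateInputError("profile has no spectral power")
    k_lo = 2  # exclude DC (k=0) and periods > n/2 (k=1)
    k_hi = min(power.size - 1, int(n / min_period))
    if k_hi < k_lo:
        raise ValueError("profile too short for the requested minimum period")
    band = power[k_lo : k_hi + 1]
    k = int(np.argmax(band)) + k_lo
    # parabolic refinement over (k-1, k, k+1)
    delta = 0.0
    if 0 < k < power.size - 1:
        p0, p1, p2 = power[k - 1], power[k], power[k + 1]
        denom = p0 - 2 * p1 + p2
        if denom != 0:
            delta = float(np.clip(0.5 * (p0 - p2) / denom, -0.5, 0.5))
    period = n / (k + delta)
    return float(period), float(power[k])


def refine_period_autocorr(profile, approx_period: float) -> float:
    """Refine a period estimate via the autocorrelation peak nearest to it.

    FFT bin spacing limits the precision of :func:`dominant_frequency` on
    short profiles; the autocorrelation lag of the repeating structure,
    refined by parabolic interpolation, recovers the period to a small
    fraction of a pixel.  Falls back to ``approx_period`` when no local
    peak exists nearby.
    """
    values = _as_values(profile)
    x = values - values.mean()
    n = x.size
    corr = signal.correlate(x, x, mode="full")[n - 1 :]  # lags 0..n-1
    lo = max(2, int(np.floor(approx_period * 0.8)))
    hi = min(n - 2, int(np.ceil(approx_period * 1.2)))
    if hi <= lo:
        return float(approx_period)
    k = lo + int(np.argmax(corr[lo : hi + 1]))
    if not (corr[k] >= corr[k - 1] and corr[k] >= corr[k + 1]):
        return float(approx_period)
    c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
    denom = c0 - 2 * c1 + c2
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    return float(k + delta)


def spectral_peak_fraction(profile) -> float:
    """Fraction of total non-DC spectral power carried by the dominant peak.

    A periodic channel comb concentrates power in one bin; noise spreads it
    evenly.  Used to decide whether a profile contains channel structure.
    """
    values = _as_values(profile)
    x = values - values.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    nondc = power[2:]
    total = nondc.sum()
    if total <= 0:
        return 0.0
    return float(nondc.max() / total)


def band_power_fraction(profile, period: float, half_bins: int = 1) -> float:
    """Share of non-DC spectral power within +-half_bins of 1/period.

    Measures whether a signal *contains* a given periodicity regardless of
    what else dominates its spectrum.
    """
    values = _as_values(profile)
    x = values - values.mean()
    n = x.size
    power = np.abs(np.fft.rfft(x)) ** 2
    total = power[1:].sum()
    if total <= 0 or period <= 0:
        return 0.0
    k = int(round(n / period))
    lo, hi = max(1, k - half_bins), min(power.size - 1, k + half_bins)
    if hi < lo:
        return 0.0
    return float(power[lo : hi + 1].sum() / total)


def otsu_threshold(values) -> float:
    """Threshold maximising inter-class variance of the intensity histogram.

    Uses a 256-bin histogram over the observed range.  The returned value is
    the upper edge of the optimal cut's bin, so that ``values <= threshold``
    reproduces exactly the partition whose inter-class variance was
    maximised (scikit-image returns the bin centre, which would flip
    samples in the upper half of that bin).  Constant input has no separable
    classes and raises :class:`DegenerateInputError`.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2 or np.unique(arr).size < 2:
        raise DegenerateInputError("Otsu threshold needs >= 2 distinct values")
    centre = float(threshold_otsu(arr, nbins=256))
    half_bin = (arr.max() - arr.min()) / 256 / 2
    return centre + half_bin
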