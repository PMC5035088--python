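# Methods

This note documents the models, algorithms and numerical choices behind
`mmtrace`, in the spirit of a methods section: what each stage assumes,
which parameters matter, and what the synthetic-data validation does and
does not demonstrate.

## Coordinate and unit conventions

Frames are indexed 0-based internally; the results table reports 1-based
time points.  Pixel coordinates are 0-based half-open intervals
`[top, bottom)`.  Images are indexed `[y, x]`; the horizontal profile
`h(x)` averages over rows, the vertical profile `v(y)` over columns.
Physical lengths are µm (via the mandatory pixel size), times are hours,
growth rates h⁻¹.  Calibration from OME-XML metadata wins over
configuration overrides; with neither, loading fails — the 1 µm cell-length
filter is meaningless without a pixel size.

## Signal primitives

*Smoothing* is convolution with a unit-sum Hamming window, reflected at the
boundaries (reflection avoids the edge droop that would fake extrema in
cell detection).  *Cross-correlation argmax* runs on mean-subtracted
signals as linear (zero-padded) correlation — drift is not cyclic; ties
break towards the smallest-magnitude lag, and flat signals return lag 0
with a warning.  Where sub-pixel resolution matters (strip shifts feeding
the rotation angle), the peak is refined by parabolic interpolation over
its 3-sample neighbourhood.  An optional search window (`center`,
`radius`) restricts the lag range when a physical bound on the shift is
known.  *Dominant period* estimation excludes DC and periods above half the
profile length and refines the peak bin parabolically.  *Otsu thresholds*
use a 256-bin histogram (scikit-image); the returned value is shifted to
the upper edge of the optimal cut's bin so that `values <= threshold`
reproduces exactly the partition whose inter-class variance was maximised.

## Registration and orientation

Drift is corrected per frame against frame 0 using the two 1D profile
correlations, at integer-pixel resolution — the downstream 1D analysis
tolerates ±1 px, and sub-pixel resampling would blur the profiles it feeds.
On a periodic channel array the correlation peak repeats every channel
interval i_C, so registration tracks drift sequentially: each frame's
search window is centred on the previous frame's shift with radius
i_C/3.  This exploits the physical continuity of stage drift and removes
the aliasing outright (without it, occasional one-interval jumps
misassigned every cell to its neighbouring channel).

Rotation uses N = 16 vertical strips of width d = W/N: each strip's
smoothed vertical profile is differenced, adjacent difference profiles are
cross-correlated to sub-pixel shifts s_n (lag bounded by tan 15° · d, the
plausibility limit for a mounted chip), shifts beyond 2σ from the median
are discarded, and θ = arctan(mean kept shift / d).  Positive θ means
features at larger x sit at larger y; correction rotates by −θ with
bilinear interpolation about the image centre, median-filled outside.  The
angle is estimated once on the first registered frame and applied to all
frames (chip rotation is physically constant; per-frame estimation is
available but adds jitter).  Recovery is within 0.1° for true angles in
[−5°, 5°] on rendered scenes; residuals after correction stay below 0.3°
on twice-interpolated images.

## Channel detection

The channel interval is estimated from the structure's horizontal profile.
Plain FFT-argmax is unreliable when channels are dense with cells (the
dark wall pattern repeats within each period and pushes the strongest peak
onto a harmonic), so the interval combines two overlap-normalised
autocorrelations — of the raw profile and of the wall-edge train |h′| —
and takes the smallest local-maximum lag within 80 % of the best score.
Half and double candidates are then fitted as full box layouts and decided
by how informatively each explains the wall-edge mass: a layout must
capture ≥ 75 % of the mass without covering more than 85 % of the profile
(a doubled period misses every other channel; a halved one covers
everything and explains nothing).

The array's vertical extent is the largest run of 16-px row strips sharing
the global periodicity; a strip matches when its dominant period is a
harmonic of the global one (±20 %) or when its wall-edge train
autocorrelates at the global interval with ratio ≥ 0.2 — cells shift a
strip's dominant peak onto harmonics or subharmonics, but the walls repeat
at i_C in every array row regardless of cell load.  Gaps of up to two
ambiguous strips are bridged.  A frame with no significant spectral peak
raises a structure-not-found error and is skipped with a warning.

Width w_C is the in-range (0, i_C) lag maximising the c_l/c_r
correlation; the reference comb a(x) has ones at round(m·i_C) and
round(m·i_C + w_C) (per-tooth rounding distributes the remainder of a
non-integer interval), and its teeth are widened ±2 px before the h_τ
product so rounding cannot drop a genuine wall.  The comb phase has a rare
ambiguity near 50 % duty cycle (the comb can lock onto the gaps); the
three phase variants φ, φ±w_C are compared by the contrast between box
interiors and their immediate flanks — a true channel is brighter than the
dark wall ridges flanking it whatever its cell load.  Boxes are comb
positions whose h_τ mass exceeds 0.4 × the upper-quartile per-tooth mass
(quartile, not mean: the mean is diluted by empty border teeth and an
individually weak channel must not fall through).

Per frame, only the phase is re-estimated against the canonical geometry
of the first frame — interval, width and array rows are physical constants
of the chip — and detected boxes are matched to canonical channels by
nearest x within i_C/2, giving every growth channel a stable identity.
On a registered drift-free stack the per-channel box positions vary with
std < 1 px.

## Cell detection

The channel crop's vertical profile is baseline-corrected by subtracting a
version of itself smoothed with a window as long as the profile, then
smoothed again (window 5 px).  Local extrema come from a sliding-window
scan (window 5 px, plateaus collapse to their centre; boundary extrema
from truncated windows are kept deliberately — the bright margins delimit
the outermost cells).  An amplitude hysteresis prunes adjacent
maximum/minimum pairs whose gap is below max(5 % of the profile range,
8 × the noise floor estimated from robust first differences), restricted
to pairs below the profile midrange: only dark-side wiggles can split a
cell, while structural maxima in bright regions must survive regardless of
their local amplitude.

Adjacent maxima pairs are cell candidates, filtered by three independent
criteria: length ≥ 1 µm; blackness ≥ 0.5, where blackness is the mean dark
fraction of the candidate's extent under Otsu binarization of the crop
(dark-cell polarity is a flag for inverted-contrast data); and prominence ≥
2 % of the crop's intensity range, where prominence is the gap between the
upper and lower envelopes (through profile maxima and minima respectively)
at the candidate centre.  Envelopes are shape-preserving (PCHIP) cubics for
≥ 4 support points and piecewise-linear otherwise — natural cubic splines
overshoot between a bright and a dark node and can push the upper envelope
below the lower one, faking zero prominence for a real cell.  Otsu runs per
crop (local robustness against illumination differences across the array).

On 200 random synthetic channels (1–8 cells, SNR ≥ 3) the detector finds
the exact cell count in ≥ 95 % of channels with a boundary MAE ≤ 2 px.

## Tracking

Between consecutive frames, cells of frame t take exactly one fate: same
(S), divide (D, two adjacent daughters — a geometric necessity in a 1D
channel), or lost (L); unclaimed frame-t+1 cells are de novo (N).  Costs
are parameterised forms: S(j,k) = w_p·Δpos² + w_l·Δlen_rel², with the
predicted position from the track's recent velocity and the predicted
length from its recent elongation factor (exponentially weighted over the
last three sightings, weights 4:2:1; cold start: zero velocity, unit
growth); D adds the deviation of the daughter pair's summed length and
midpoint, a small asymmetry penalty and a constant division bias; N and L
are flat penalties (default 5.0) exceeding typical movement costs.
Defaults: w_p = 1 µm⁻², w_l = 5.  All coefficients are configuration
values, so alternative cost forms can be dropped in without touching the
solver.

Feasible assignments under the one-fate and non-crossing constraints are
exactly the order-preserving fate sequences, so the per-frame-pair
minimisation is solved exactly by a dynamic program over (frame-t cell,
first available daughter) in O(J·K²); the test suite checks it against
exhaustive enumeration of all feasible assignments on small instances.  A
greedy "cheapest fate first" construction was evaluated and abandoned: on
random cost instances it deviated grossly from the optimum (it happily
burns an appearance and a loss penalty to grab one cheap link), and local
improvement moves did not close the gap reliably.

Assignments chain into a lineage tree per channel: a division ends the
parent track and starts exactly two daughter tracks; tracks end at a loss
or at the final frame; frames where detection failed are bridged as a
single step with the movement tolerance widened proportionally.  Missed
divisions are detected late rather than lost (the seam between daughters
only needs to become visible), which leaves division counts and mean
division times nearly unbiased; the residual undercount comes from
daughters flushed at the open end before their seam resolves.

## Quantification

A division event's time is measured from the parent's own birth division
to its division, so tracks born de novo (first frame, or entering mid
series) contribute no event — this avoids biased short/long times.  Events
whose implied µ = ln 2 / t_d falls outside loose physiological bounds
(default 0.01–1.0 h⁻¹) are discarded as tracking artifacts.  The
moving-average growth-rate curve uses a 25-event rolling window sampled on
a time grid, undefined wherever a bin holds fewer than 5 events.
Precision/recall against a reference event table uses greedy one-to-one
matching by ascending Manhattan distance in (occurrence frame, division
age), with both coordinates bounded by the allowed frame offset.
Fluorescence is the mean over the cell's bounding box minus the mean of
the device structure between the channels (central 50 % of each
inter-channel gap, restricted to the array rows), evaluated only at time
points where a fluorescence frame was acquired — missing frames stay
missing.  Exports are a tab-separated per-sighting table and per-channel
kymographs (channel crops tiled in frame order, one polyline per track
through the sighting centroids, forking at divisions).

## Synthetic scenes

The simulator emulates what the pipeline consumes: a horizontal array of
evenly spaced bright channels (default 20 channels, i_C = 30 px,
w_C = 12 px) flanked by dark 2-px wall ridges on a mid-gray device band
over a darker background, dark mid-gray rod cells filling the channel
width, a cell-free junction region at the open end, global rotation,
bounded random-walk drift, a smooth illumination field, a 1-px Gaussian
blur and additive Gaussian noise (default σ = 5 % of the dynamic range).
Cell kinetics run in continuous time: exponential elongation with per-cell
doubling times (default 1.3 h, 5 % CV), division at a threshold length
(3.0 ± 0.15 µm) with an asymmetry ratio drawn around 0.5 (σ = 0.05,
truncated to [0.35, 0.65]), and continuous flushing — a cell protruding
past the open end at a division instant is removed before it can divide,
so every recorded division is observable in principle.  Division instants
are exact; frames are snapshots, so scripted division intervals carry no
frame quantization.  Cells are drawn with 0.8-px end caps, producing the
bright seam a septum shows in phase contrast; phase-contrast halos are not
modelled (nothing in the pipeline relies on them).  Frames are stored as
uint16 (intensity × 10⁴) for lossless TIFF round-trips, and all randomness
derives from a single seed (identical seeds give bit-identical stacks).

What passing synthetic tests shows: the pipeline's geometry, detection and
tracking logic recover scripted truth under realistic noise, drift,
rotation and illumination.  What it does not show: robustness to optics the
renderer omits — phase halos, focus drift, debris, biofilm growth, cell
width variation — for which the detection thresholds and cost coefficients
may need retuning on real data (the interactive preview exists for exactly
that).

## Validation battery and problem sizes

`scripts/acceptance.py --seed N --out results.json` regenerates every
reported number.  Problem sizes are chosen to keep the battery at a few
minutes on one CPU: the end-to-end recovery runs the full 20-channel,
240-frame reference scene; the imaging-interval study uses five 6-channel
replicates at strides 1–6 (division-time SD rises monotonically with the
stride, Spearman ρ ≈ 1); geometry recovery uses 100 single-frame random
scenes (interval 20–60 px, width 6–14 px, noise up to 10 %); detection
accuracy uses 200 random channel crops.  On the reference scene the
recovered mean division time agrees with the scripted value to a few
thousandths of an hour (tolerance: one 5-min frame interval) and the
division count to within 5 % (typically −2 to −4 %, the unobservable
flushed-seam events described above).

## Known limitations

- Straight, evenly spaced channel combs only; 2D growth chambers and
  strongly curved arrays are out of scope.
- Integer-pixel registration; sub-pixel drift shows up as ±1 px boundary
  jitter.
- A division whose daughter is flushed before the inter-daughter seam
  becomes visible is recorded as a loss, a 2–4 % undercount at the default
  geometry.
- Two divisions of the same lineage within a single bridged gap cannot be
  represented (disallowed by the fate model).
- The cost coefficients are package defaults validated on synthetic
  scenes, not fitted to any particular instrument.
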