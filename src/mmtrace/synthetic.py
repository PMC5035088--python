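"""Synthetic mother-machine scenes with full ground truth.

The simulator produces time-lapse stacks that look like phase-contrast
mother-machine data to the profile-based pipeline: a horizontal array of
evenly spaced bright vertical growth channels on a darker device background,
dark rod-shaped cells stacked without overlap inside the channels, global
frame drift, a small global rotation, smooth uneven illumination and
additive Gaussian noise.  Biology follows the mother-machine regime: the
mother cell sits at the dead end, elongates exponentially, divides when it
reaches a (noisy) threshold length, and pushes its progeny towards the open
end where cells are flushed away.

Cell kinetics run in continuous time (division instants are exact, frames
are snapshots), so scripted division intervals are free of frame
quantization; the pipeline's recovered intervals are compared against them.
Phase-contrast halos are not modelled: a three-level intensity model with a
small Gaussian blur is sufficient for profile-based detection, and cell ends
are shrunk slightly so that stacked cells show the realistic bright seam a
septum produces.

Every random draw derives from ``SceneConfig.seed``; identical config and
seed give bit-identical stacks and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_stack import Calibration, FrameSeries

PHASE_SCALE = 10000.0  # float [0, ~1.3] -> uint16 storage


@dataclass
class GrowthParams:
    """Kinetics of the simulated population.

    Cells elongate exponentially with per-cell doubling time
    ``doubling_time_h`` (log-normal cell-to-cell variability ``rate_cv``)
    and divide on reaching ``division_length_um`` plus threshold noise;
    daughters split the parent with an asymmetry ratio drawn around 0.5.
    Defaults give the 2-3 um rod regime of coryne-/enterobacteria growing
    with t_d around 1.3 h.
    """

    doubling_time_h: float = 1.3
    division_length_um: float = 3.0
    division_length_sd_um: float = 0.15
    rate_cv: float = 0.05
    asymmetry_sd: float = 0.05


@dataclass
class FluorParams:
    """Optional fluorescence channel with a sparser acquisition schedule.

    Cells emit ``low_au`` before ``switch_frame`` and ``high_au`` after
    (emulating a biosensor switching on after a medium change); the device
    structure has constant autofluorescence ``structure_au`` which the
    quantification stage must subtract as background.
    """

    name: str = "yfp"
    period_frames: int = 12
    switch_frame: int | None = None
    low_au: float = 16.0
    high_au: float = 330.0
    cell_sd_au: float = 2.0
    structure_au: float = 30.0
    noise_sigma_au: float = 1.0


@dataclass
class SceneConfig:
    """Geometry, optics and acquisition of a synthetic scene.

    Lengths are pixels unless suffixed ``_um``; the defaults model a
    20-channel array imaged at 0.065 um/px every 5 minutes.
    """

    width_px: int = 680
    height_px: int = 330
    n_channels: int = 20
    interval_px: float = 30.0
    channel_width_px: int = 12
    phase_px: float = 28.0  # x of the first channel's left wall
    array_top: int = 50
    array_bottom: int = 280
    closed_end: str = "top"
    closed_margin_px: int = 6
    open_margin_px: int = 30  # cell-free junction towards the flow channel
    rotation_deg: float = 0.0
    drift_step_px: float = 0.0  # std of the random-walk step
    drift_linear_px: tuple[float, float] = (0.0, 0.0)  # per-frame linear drift
    drift_max_px: int = 40
    noise_sigma: float = 0.05  # fraction of dynamic range
    illumination_amplitude: float = 0.05
    background_level: float = 0.25
    device_level: float = 0.40  # solid device material between the channels
    wall_level: float = 0.18  # dark PDMS ridge flanking each channel lumen
    wall_px: int = 2
    channel_level: float = 0.75
    cell_level: float = 0.32  # phase-contrast cells are mid-gray, not black
    cell_cap_px: float = 0.8  # end shrink producing the inter-cell seam
    blur_sigma_px: float = 1.0
    pixel_size_um: float = 0.065
    frame_interval_min: float = 5.0
    n_frames: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channel_width_px < self.interval_px:
            raise ValueError("channel width must be smaller than the interval")
        if self.phase_px + self.n_channels * self.interval_px > self.width_px:
            raise ValueError("channel array does not fit into the frame width")
        if not 0 <= self.array_top < self.array_bottom <= self.height_px:
            raise ValueError("invalid array rows")

    @property
    def zone_um(self) -> float:
        """Usable channel length for cells, in um."""
        zone_px = (
            self.array_bottom
            - self.array_top
            - self.closed_margin_px
            - self.open_margin_px
        )
        return zone_px * self.pixel_size_um

    @property
    def dt_h(self) -> float:
        return self.frame_interval_min / 60.0

    def channel_left(self, index: int) -> int:
        return int(round(self.phase_px + index * self.interval_px))


@dataclass
class CellState:
    """One live simulated cell."""

    cell_id: int
    channel: int
    parent_id: int | None
    birth_time_h: float
    birth_length_um: float
    rate_per_h: float  # exponential elongation rate ln(2)/td_cell
    division_length_um: float
    birth_by_division: bool
    fluor_au: float = 0.0

    def length_at(self, t_h: float) -> float:
        return self.birth_length_um * np.exp(self.rate_per_h * (t_h - self.birth_time_h))

    def division_time_h(self) -> float:
        return self.birth_time_h + (
            np.log(self.division_length_um / self.birth_length_um) / self.rate_per_h
        )


@dataclass
class DivisionTruth:
    channel: int
    time_h: float
    frame: int  # first frame at/after the division instant
    parent_id: int
    daughter_ids: tuple[int, int]
    parent_birth_time_h: float
    parent_birth_by_division: bool


@dataclass
class GroundTruth:
    """Everything the renderer knows: geometry, lineage, extents, transforms."""

    config: SceneConfig
    growth: GrowthParams
    divisions: list[DivisionTruth] = field(default_factory=list)
    flushes: list[tuple[int, float, int]] = field(default_factory=list)
    # per frame: channel -> list of (cell_id, top_px, bottom_px) in scene rows
    extents: list[dict[int, list[tuple[int, float, float]]]] = field(default_factory=list)
    drift: np.ndarray | None = None  # (T, 2) int (dx, dy)

    def n_sightings(self) -> int:
        return sum(len(v) for frame in self.extents for v in frame.values())

    def scripted_division_count(self) -> int:
        return len(self.divisions)

    def scripted_intervals_h(self) -> np.ndarray:
        """Birth-division to division spacing, for parents born by division."""
        return np.array(
            [
                d.time_h - d.parent_birth_time_h
                for d in self.divisions
                if d.parent_birth_by_division
            ]
        )


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_lineage(
    config: SceneConfig, growth: GrowthParams | None = None
) -> GroundTruth:
    """Run the continuous-time birth/division/flush process for all channels.

    Initial cells are seeded mid-cycle at random phases so channels are
    desynchronised.  Divisions are processed at their exact instants between
    frames; flushing (a cell's open-end boundary passing the channel end) is
    applied at frame granularity, which is when it becomes observable.
    """
    growth = growth or GrowthParams()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = GroundTruth(config=config, growth=growth)
    next_id = 0

    def sample_rate() -> float:
        td = growth.doubling_time_h * float(
            np.exp(rng.normal(0.0, growth.rate_cv))
        )
        return float(np.log(2) / td)

    def sample_threshold() -> float:
        return float(
            max(
                growth.division_length_um
                + rng.normal(0.0, growth.division_length_sd_um),
                0.5,
            )
        )

    def make_cell(
        channel: int,
        parent: int | None,
        birth_time: float,
        birth_length: float,
        by_division: bool,
    ) -> CellState:
        nonlocal next_id
        cell = CellState(
            cell_id=next_id,
            channel=channel,
            parent_id=parent,
            birth_time_h=birth_time,
            birth_length_um=birth_length,
            rate_per_h=sample_rate(),
            division_length_um=sample_threshold(),
            birth_by_division=by_division,
            fluor_au=0.0,
        )
        next_id += 1
        return cell

    channels: list[list[CellState]] = []
    for ch in range(config.n_channels):
        # seed 2-4 cells mid-cycle, mother first (closed end)
        n0 = int(rng.integers(2, 5))
        cells = []
        for _ in range(n0):
            thr = sample_threshold()
            phase = rng.uniform(0.05, 0.95)
            birth_len = 0.5 * thr
            # place the cell a fraction `phase` through its cycle at t=0
            rate = sample_rate()
            birth_time = -phase * np.log(thr / birth_len) / rate
            cell = make_cell(ch, None, birth_time, birth_len, False)
            cell.rate_per_h = rate
            cell.division_length_um = thr
            cells.append(cell)
        channels.append(cells)

    times = np.arange(config.n_frames) * config.dt_h
    if growth.doubling_time_h <= 0 or not np.isfinite(growth.doubling_time_h):
        raise ValueError("doubling_time_h must be positive")

    for frame, t in enumerate(times):
        frame_extents: dict[int, list[tuple[int, float, float]]] = {}
        for ch in range(config.n_channels):
            cells = channels[ch]
            # process divisions up to time t, earliest first; the flow sweeps
            # protruding cells away continuously, so flushing is applied at
            # each division instant before the division may happen
            while True:
                if not cells:
                    break
                tdivs = [c.division_time_h() for c in cells]
                i = int(np.argmin(tdivs))
                if tdivs[i] > t:
                    break
                tdiv = tdivs[i]
                lengths_now = [c.length_at(tdiv) for c in cells]
                bottoms_now = np.cumsum(lengths_now)
                keep_now = bottoms_now <= config.zone_um
                if not keep_now.all():
                    for c, k in zip(cells, keep_now):
                        if not k:
                            truth.flushes.append((ch, float(tdiv), c.cell_id))
                    cells[:] = [c for c, k in zip(cells, keep_now) if k]
                    continue  # indices changed; re-pick the earliest division
                parent = cells[i]
                r = _truncated_normal(
                    rng, 0.5, growth.asymmetry_sd, 0.35, 0.65
                )
                ld = parent.division_length_um
                upper = make_cell(ch, parent.cell_id, tdiv, r * ld, True)
                lower = make_cell(ch, parent.cell_id, tdiv, (1 - r) * ld, True)
                cells[i : i + 1] = [upper, lower]
                truth.divisions.append(
                    DivisionTruth(
                        channel=ch,
                        time_h=float(tdiv),
                        frame=frame,
                        parent_id=parent.cell_id,
                        daughter_ids=(upper.cell_id, lower.cell_id),
                        parent_birth_time_h=parent.birth_time_h,
                        parent_birth_by_division=parent.birth_by_division,
                    )
                )
            # positions at time t, stacked from the closed end
            lengths = [c.length_at(t) for c in cells]
            tops = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
            bottoms = tops + lengths
            # flush cells protruding past the open end
            keep = bottoms <= config.zone_um
            for c, k in zip(cells, keep):
                if not k:
                    truth.flushes.append((ch, float(t), c.cell_id))
            channels[ch] = [c for c, k in zip(cells, keep) if k]
            px = config.pixel_size_um
            row0 = config.array_top + config.closed_margin_px
            frame_extents[ch] = [
                (c.cell_id, row0 + top / px, row0 + bottom / px)
                for c, top, bottom, k in zip(cells, tops, bottoms, keep)
                if k
            ]
        truth.extents.append(frame_extents)
    return truth


def _illumination_field(config: SceneConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    h, w = config.height_px, config.width_px
    y, x = np.mgrid[0:h, 0:w]
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    field = 0.5 * (
        np.sin(np.pi * x / w + p1) + np.sin(np.pi * y / h + p2)
    )
    return config.illumination_amplitude * field


def drift_trajectory(config: SceneConfig) -> np.ndarray:
    """Integer per-frame drift: bounded random walk plus linear component."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    steps = rng.normal(0.0, config.drift_step_px, size=(config.n_frames, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    lin = np.outer(np.arange(config.n_frames), np.asarray(config.drift_linear_px))
    traj = np.clip(walk + lin, -config.drift_max_px, config.drift_max_px)
    traj[0] = 0.0
    return np.round(traj).astype(int)


def _paint_cells(
    image: np.ndarray,
    extents: list[tuple[int, float, float]],
    left: int,
    right: int,
    level: float,
    cap_px: float,
) -> None:
    """Paint dark cells with sub-pixel end coverage into the clean scene."""
    h = image.shape[0]
    for _cid, top, bottom in extents:
        lo = top + cap_px
        hi = bottom - cap_px
        if hi <= lo:
            continue
        r0 = max(0, int(np.floor(lo)))
        r1 = min(h, int(np.ceil(hi)))
        cols = slice(max(0, left), right)
        for row in range(r0, r1):
            cover = min(row + 1.0, hi) - max(float(row), lo)
            if cover <= 0:
                continue
            alpha = min(1.0, cover)
            image[row, cols] = (1 - alpha) * image[row, cols] + alpha * level


def render_frame(
    extents: dict[int, list[tuple[int, float, float]]],
    config: SceneConfig,
    frame_index: int,
    drift: tuple[int, int] = (0, 0),
    illumination: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame: scene, blur, rotation, drift, illumination, noise.

    Deterministic given the scene seed and ``frame_index``.
    """
    cfg = config
    img = np.full((cfg.height_px, cfg.width_px), cfg.background_level)
    img[cfg.array_top : cfg.array_bottom, :] = cfg.device_level
    for ch in range(cfg.n_channels):
        left = cfg.channel_left(ch)
        right = left + cfg.channel_width_px
        rows = slice(cfg.array_top, cfg.array_bottom)
        img[rows, max(0, left - cfg.wall_px) : left] = cfg.wall_level
        img[rows, right : right + cfg.wall_px] = cfg.wall_level
        img[rows, left:right] = cfg.channel_level
        _paint_cells(
            img,
            extents.get(ch, []),
            left,
            right,
            cfg.cell_level,
            cfg.cell_cap_px,
        )
    if cfg.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.rotation_deg != 0.0:
        img = ndimage.rotate(
            img,
            angle=-cfg.rotation_deg,
            reshape=False,
            order=1,
            mode="constant",
            cval=cfg.background_level,
        )
    dx, dy = drift
    if dx or dy:
        from .registration import ShiftVector, apply_shift

        img = apply_shift(img, ShiftVector(int(dx), int(dy)), fill=cfg.background_level)
    if illumination is not None:
        img = img + illumination
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 4, frame_index])
        )
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return img


def _render_fluor_frame(
    extents: dict[int, list[tuple[int, float, float]]],
    cell_values: dict[int, float],
    config: SceneConfig,
    fluor: FluorParams,
    frame_index: int,
    drift: tuple[int, int],
) -> np.ndarray:
    cfg = config
    img = np.full((cfg.height_px, cfg.width_px), fluor.structure_au)
    for ch in range(cfg.n_channels):
        left = cfg.channel_left(ch)
        right = left + cfg.channel_width_px
        for cid, top, bottom in extents.get(ch, []):
            r0 = max(0, int(round(top)))
            r1 = min(cfg.height_px, int(round(bottom)))
            img[r0:r1, left:right] = fluor.structure_au + cell_values[cid]
    if cfg.rotation_deg != 0.0:
        img = ndimage.rotate(
            img,
            angle=-cfg.rotation_deg,
            reshape=False,
            order=1,
            mode="constant",
            cval=fluor.structure_au,
        )
    dx, dy = drift
    if dx or dy:
        from .registration import ShiftVector, apply_shift

        img = apply_shift(img, ShiftVector(int(dx), int(dy)), fill=fluor.structure_au)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 5, frame_index])
    )
    return img + rng.normal(0.0, fluor.noise_sigma_au, size=img.shape)


def generate_stack(
    config: SceneConfig,
    growth: GrowthParams | None = None,
    fluor: FluorParams | None = None,
) -> tuple[FrameSeries, GroundTruth]:
    """Simulate a lineage and render the full stack (plus optional fluorescence).

    Phase-contrast frames are stored as uint16 (intensity x 10000) so stacks
    round-trip losslessly through TIFF.
    """
    growth = growth or GrowthParams()
    truth = simulate_lineage(config, growth)
    truth.drift = drift_trajectory(config)
    illum = _illumination_field(config) if config.illumination_amplitude else None

    frames = np.empty(
        (config.n_frames, config.height_px, config.width_px), dtype=np.uint16
    )
    for f in range(config.n_frames):
        img = render_frame(
            truth.extents[f],
            config,
            frame_index=f,
            drift=tuple(truth.drift[f]),
            illumination=illum,
        )
        frames[f] = np.clip(img * PHASE_SCALE, 0, 65535).astype(np.uint16)

    fluorescence: dict[str, list[np.ndarray | None]] = {}
    if fluor is not None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
        values: dict[int, float] = {}
        seq: list[np.ndarray | None] = [None] * config.n_frames
        for f in range(0, config.n_frames, fluor.period_frames):
            level = (
                fluor.high_au
                if fluor.switch_frame is not None and f >= fluor.switch_frame
                else fluor.low_au
            )
            for ext in truth.extents[f].values():
                for cid, _t, _b in ext:
                    values[cid] = float(
                        max(0.0, rng.normal(level, fluor.cell_sd_au))
                    )
            seq[f] = _render_fluor_frame(
                truth.extents[f], values, config, fluor, f, tuple(truth.drift[f])
            ).astype(np.float32)
        fluorescence[fluor.name] = seq

    series = FrameSeries(
        frames=frames,
        calibration=Calibration(
            pixel_size_um=config.pixel_size_um,
            frame_interval_min=config.frame_interval_min,
        ),
        fluorescence=fluorescence,
        position_id=f"synthetic-{config.seed}",
    )
    return series, truth


def render_channel_crop(
    cell_intervals_px: list[tuple[float, float]],
    height_px: int = 230,
    width_px: int = 12,
    channel_level: float = 0.75,
    cell_level: float = 0.32,
    background_level: float = 0.30,
    cap_px: float = 0.8,
    blur_sigma_px: float = 1.0,
    noise_sigma: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a single channel crop (for detector-level tests).

    ``cell_intervals_px`` are (top, bottom) rows of dark cells inside the
    crop; the rest of the crop is bright channel interior.
    """
    img = np.full((height_px, width_px), channel_level)
    _paint_cells(
        img,
        [(i, t, b) for i, (t, b) in enumerate(cell_intervals_px)],
        left=0,
        right=width_px,
        level=cell_level,
        cap_px=cap_px,
    )
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img
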