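"""Self-contained benchmark studies on synthetic scenes.

Each function generates its own synthetic data with full ground truth, runs
the relevant pipeline stage(s) end-to-end, and returns measured recovery
statistics.  They power the validation suite and the reproduction script;
problem sizes are chosen so the whole battery runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as scipy_stats

from .cells import DetectionParams, detect_cells
from .channels import detect_geometry
from .io_stack import Calibration, subsample
from .pipeline import PipelineParams, analyze_series
from .quantify import division_time_stats, division_times, growth_rate
from .registration import ShiftVector, estimate_rotation, estimate_shift, rotate_image
from .synthetic import (
    GrowthParams,
    SceneConfig,
    generate_stack,
    render_channel_crop,
    render_frame,
    simulate_lineage,
)

REFERENCE_DOUBLING_TIME_H = 1.3


def growth_rate_identities() -> dict:
    """Growth rates implied by the benchmark doubling times, mu = ln2/t_d."""
    return {
        "mu_from_td_1.27h": round(growth_rate(1.27), 2),
        "mu_from_td_1.33h": round(growth_rate(1.33), 2),
        "mu_from_td_1.72h": round(growth_rate(1.72), 2),
        "mu_from_td_1.73h": round(growth_rate(1.73), 2),
    }


def reference_scene(seed: int, **overrides) -> SceneConfig:
    """The 20-channel, 240-frame, 5-min-interval reference scene."""
    params = dict(
        seed=seed,
        rotation_deg=0.8,
        drift_step_px=0.4,
        n_frames=240,
    )
    params.update(overrides)
    return SceneConfig(**params)


def full_pipeline_recovery(seed: int) -> dict:
    """Analyze the reference scene end-to-end and compare with its script.

    Returns the recovered mean/SD division time, the division-count
    relative error, and the implied growth rate.
    """
    config = reference_scene(seed)
    series, truth = generate_stack(
        config, GrowthParams(doubling_time_h=REFERENCE_DOUBLING_TIME_H)
    )
    result = analyze_series(series)
    stats = division_time_stats(division_times(result.tree))
    scripted = truth.scripted_division_count()
    intervals = truth.scripted_intervals_h()
    return {
        "n_frames": config.n_frames,
        "n_channels": config.n_channels,
        "scripted_doubling_time_h": REFERENCE_DOUBLING_TIME_H,
        "scripted_divisions": scripted,
        "recovered_divisions": result.counters.divisions,
        "division_count_rel_error": (result.counters.divisions - scripted) / scripted,
        "recovered_mean_td_h": stats.mean_td_h,
        "recovered_sd_td_h": stats.sd_td_h,
        "scripted_mean_td_h": float(intervals.mean()),
        "td_abs_error_h": abs(stats.mean_td_h - float(intervals.mean())),
        "recovered_mu_per_h": stats.mu_per_h,
        "n_events": stats.n_events,
        "cell_sightings": result.counters.cell_sightings,
    }


def stride_degradation(seed: int, n_replicates: int = 5,
                       strides=(1, 2, 3, 4, 5, 6)) -> dict:
    """Division-time SD versus frame subsampling stride.

    Uses 6-channel replicates of the reference conditions so five seeds x
    six strides stay tractable; reports the per-seed Spearman correlation
    between stride and SD and its mean.
    """
    rhos = []
    sds_by_seed = []
    for r in range(n_replicates):
        config = reference_scene(
            seed + 100 + r, n_channels=6, width_px=260, phase_px=28.0,
            rotation_deg=0.5, drift_step_px=0.3,
        )
        series, _truth = generate_stack(
            config, GrowthParams(doubling_time_h=REFERENCE_DOUBLING_TIME_H)
        )
        sds = []
        for stride in strides:
            result = analyze_series(subsample(series, stride))
            stats = division_time_stats(division_times(result.tree))
            sds.append(stats.sd_td_h)
        rhos.append(float(scipy_stats.spearmanr(strides, sds).statistic))
        sds_by_seed.append(sds)
    return {
        "strides": list(strides),
        "sd_td_h_by_seed": sds_by_seed,
        "spearman_by_seed": rhos,
        "mean_spearman": float(np.mean(rhos)),
    }


def rotation_recovery(seed: int, angles_deg=(-5.0, -3.0, -1.0, 1.0, 3.0, 5.0)) -> dict:
    """Rotate a rendered scene by known angles and re-estimate each."""
    config = reference_scene(seed, n_frames=1, rotation_deg=0.0,
                             drift_step_px=0.0)
    truth = simulate_lineage(config, GrowthParams())
    base = render_frame(truth.extents[0], config, 0)
    errors = []
    for angle in angles_deg:
        rotated = rotate_image(base, np.deg2rad(angle))
        est = estimate_rotation(rotated)
        errors.append(abs(est.theta_deg - angle))
    return {"angles_deg": list(angles_deg), "max_error_deg": float(max(errors))}


def drift_recovery(seed: int, n_frames: int = 60) -> dict:
    """Track a bounded random-walk drift and report the worst per-frame error."""
    config = reference_scene(seed, n_frames=n_frames, rotation_deg=0.0,
                             drift_step_px=1.0, drift_max_px=80)
    series, truth = generate_stack(config, GrowthParams())
    ref = series.frames[0].astype(float)
    prev = ShiftVector(0, 0)
    errors = []
    for f in range(series.n_frames):
        prev = estimate_shift(ref, series.frames[f], center=prev, radius=10)
        errors.append(
            max(abs(prev.dx - truth.drift[f][0]), abs(prev.dy - truth.drift[f][1]))
        )
    return {"max_error_px": float(max(errors)), "n_frames": n_frames}


def geometry_recovery(seed: int, n_scenes: int = 100) -> dict:
    """Channel count and box positions over random scene configurations."""
    rng = np.random.default_rng(seed)
    correct = 0
    box_errors = []
    for i in range(n_scenes):
        interval = float(rng.uniform(20, 60))
        width = int(rng.integers(6, 15))
        n_ch = int(rng.integers(5, 12))
        config = SceneConfig(
            width_px=int(n_ch * interval + 80),
            height_px=260,
            n_channels=n_ch,
            interval_px=interval,
            channel_width_px=width,
            phase_px=float(rng.uniform(20, 20 + interval)),
            array_top=40,
            array_bottom=220,
            noise_sigma=float(rng.uniform(0.0, 0.10)),
            n_frames=1,
            seed=int(rng.integers(0, 2**20)),
        )
        series, _truth = generate_stack(config, GrowthParams())
        try:
            geom = detect_geometry(series.frames[0].astype(float))
        except Exception:
            continue
        if geom.n_channels == n_ch:
            correct += 1
            for k, (left, _right) in enumerate(geom.channel_boxes):
                box_errors.append(abs(left - config.channel_left(k)))
    return {
        "n_scenes": n_scenes,
        "count_accuracy": correct / n_scenes,
        "max_box_error_px": float(max(box_errors)) if box_errors else float("nan"),
    }


def detection_accuracy(seed: int, n_channels: int = 200) -> dict:
    """Cell-count accuracy and boundary MAE on random channel crops, SNR >= 3."""
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_um=0.065, frame_interval_min=5.0)
    exact = 0
    errors = []
    for _ in range(n_channels):
        height = 230
        n_cells = int(rng.integers(1, 9))
        top, cells = 6.0, []
        for _ in range(n_cells):
            length = rng.uniform(1.2, 3.2) / cal.pixel_size_um
            if top + length > height - 30:
                break
            cells.append((top, top + length))
            top += length
        noise = float(rng.uniform(0.02, 0.14))
        crop = render_channel_crop(cells, height_px=height, noise_sigma=noise,
                                   rng=rng)
        accepted = detect_cells(crop, DetectionParams(), cal)
        if len(accepted) == len(cells):
            exact += 1
            for (t, b), cand in zip(cells, accepted):
                errors += [abs(t - cand.top_px), abs(b - cand.bottom_px)]
    return {
        "n_channels": n_channels,
        "count_accuracy": exact / n_channels,
        "boundary_mae_px": float(np.mean(errors)) if errors else float("nan"),
    }
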