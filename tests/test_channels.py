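"""Channel-array localisation: extent, interval, width, phase, boxes."""

import numpy as np
import pytest

from mmtrace.channels import (
    ChannelDetectionParams,
    ChannelGeometry,
    build_reference_signal,
    channel_width,
    detect_frame_boxes,
    detect_geometry,
    edge_signals,
    estimate_phase,
    extract_channels,
    find_vertical_extent,
    match_channels,
    robust_channel_signal,
)
from mmtrace.errors import GeometryError, StructureNotFoundError
from mmtrace.signal_core import HORIZONTAL, Profile, mean_profile, smooth
from mmtrace.synthetic import GrowthParams, SceneConfig, generate_stack


def _clean_scene(**kw):
    defaults = dict(
        n_channels=8, width_px=320, n_frames=1, seed=9, noise_sigma=0.02,
        phase_px=25.0,
    )
    defaults.update(kw)
    config = SceneConfig(**defaults)
    series, truth = generate_stack(config, GrowthParams())
    return config, series.frames[0].astype(float), truth


class TestVerticalExtent:
    def test_synthetic_extent_within_one_strip(self):
        config, frame, _truth = _clean_scene(
            height_px=512, array_top=120, array_bottom=320
        )
        top, bottom = find_vertical_extent(frame, strip_height_px=16)
        assert abs(top - 120) <= 16
        assert abs(bottom - 320) <= 16

    def test_all_structure_image_returns_full_height(self):
        config, frame, _t = _clean_scene(
            height_px=240, array_top=0, array_bottom=240,
            closed_margin_px=6, open_margin_px=30,
        )
        top, bottom = find_vertical_extent(frame)
        assert top == 0
        assert bottom == 240

    def test_noise_image_raises(self):
        noise = np.random.default_rng(0).normal(size=(200, 300))
        with pytest.raises(StructureNotFoundError):
            find_vertical_extent(noise)


class TestChannelWidth:
    def test_synthetic_comb_width_within_one_pixel(self):
        _c, frame, _t = _clean_scene(interval_px=30.0, channel_width_px=10)
        top, bottom = find_vertical_extent(frame)
        h = smooth(mean_profile(frame[top:bottom], HORIZONTAL), 5)
        assert channel_width(h, 30.0) == pytest.approx(10, abs=1)

    def test_matches_brute_force_scan_on_triangular_bumps(self):
        x = np.zeros(300)
        for start in range(20, 280, 30):
            x[start : start + 8] = 1.0 - np.abs(np.linspace(-1, 1, 8))
        c_l, c_r = edge_signals(x)
        brute = max(
            range(1, 30),
            key=lambda l: float(np.dot(c_l[: c_l.size - l], c_r[l:])),
        )
        assert channel_width(x, 30.0) == brute

    def test_flat_profile_is_geometry_error(self):
        with pytest.raises(GeometryError):
            channel_width(np.full(100, 2.0), 30.0)


class TestReferenceSignal:
    def test_hand_evaluated_positions(self):
        a = build_reference_signal(30, 10, 90)
        assert sorted(np.flatnonzero(a.values)) == [0, 10, 30, 40, 60, 70]

    def test_half_interval_width_gives_uniform_spacing(self):
        a = build_reference_signal(30, 15, 120)
        assert np.array_equal(np.flatnonzero(a.values), np.arange(0, 120, 15))

    def test_tooth_count_matches_interval_count(self):
        length, interval = 400, 27.5
        a = build_reference_signal(interval, 9, length)
        n_repeats = int(np.ceil(length / interval))
        assert abs(a.values.sum() - 2 * n_repeats) <= 2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_reference_signal(30, 30, 90)


class TestPhase:
    def test_aligned_edges_give_zero_phase(self):
        a = build_reference_signal(30, 10, 300)
        assert estimate_phase(a, a.values.copy(), 30.0) == pytest.approx(0.0)

    def test_shifted_comb_phase_matches_brute_force(self):
        a = build_reference_signal(30, 10, 300)
        shifted = np.roll(a.values, 13)
        brute = max(
            range(30),
            key=lambda s: float(np.dot(np.roll(a.values, s), shifted)),
        )
        assert estimate_phase(a, shifted, 30.0) == pytest.approx(brute) == 13

    def test_phase_periodicity_in_h_tau(self):
        a = build_reference_signal(30, 10, 300)
        c_l = np.random.default_rng(2).random(300)
        c_r = np.random.default_rng(3).random(300)
        h1 = robust_channel_signal(a, 7.0, c_l, c_r)
        h2 = robust_channel_signal(a, 7.0 + 30.0, c_l, c_r)
        # a full-interval phase offset shifts the comb by one tooth: the
        # weighted signal agrees away from the leading interval
        assert np.allclose(h1[60:], h2[60:])

    def test_degenerate_edges_rejected(self):
        a = build_reference_signal(30, 10, 300)
        with pytest.raises(GeometryError):
            estimate_phase(a, np.zeros(300), 30.0)


class TestRobustChannelSignal:
    def test_unit_weight_passes_edge_sum(self):
        c_l = np.random.default_rng(0).random(100)
        c_r = np.random.default_rng(1).random(100)
        ones = np.ones(100)
        assert np.allclose(robust_channel_signal(ones, 0.0, c_l, c_r), c_l + c_r)

    def test_zero_comb_nulls_everything(self):
        c_l = np.random.default_rng(0).random(100)
        assert not robust_channel_signal(np.zeros(100), 0.0, c_l, c_l).any()

    def test_zero_away_from_comb_teeth(self):
        a = build_reference_signal(30, 10, 300)
        h_tau = robust_channel_signal(a, 0.0, np.ones(300), np.ones(300))
        teeth = np.flatnonzero(a.values)
        far = np.ones(300, dtype=bool)
        for t in teeth:
            far[max(0, t - 2) : t + 3] = False
        assert not h_tau[far].any()


class TestExtractChannels:
    def test_exact_count_and_positions_on_synthetic_scene(self):
        config, frame, _t = _clean_scene(n_channels=10, width_px=380)
        geom = detect_geometry(frame)
        assert geom.n_channels == 10
        for k, (left, _right) in enumerate(geom.channel_boxes):
            assert abs(left - config.channel_left(k)) <= 1

    def test_border_margins_rejected(self):
        # generous channel-free margins: comb teeth there carry no mass
        config, frame, _t = _clean_scene(n_channels=5, width_px=360, phase_px=90.0)
        geom = detect_geometry(frame)
        assert geom.n_channels == 5
        assert geom.channel_boxes[0][0] >= 80

    def test_empty_channels_still_detected(self):
        """Detection relies on device walls, not on cells being present."""
        config = SceneConfig(
            n_channels=8, width_px=320, n_frames=1, seed=4, phase_px=25.0
        )
        from mmtrace.synthetic import render_frame

        frame = render_frame({}, config, 0)  # no cells at all
        geom = detect_geometry(frame)
        assert geom.n_channels == 8


class TestGeometryRandomScenes:
    def test_count_exact_and_boxes_within_one_pixel(self):
        """100 random configurations: interval 20-60 px, width 6-14 px,
        noise up to 10 % of the dynamic range."""
        rng = np.random.default_rng(42)
        box_errors = []
        for i in range(100):
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
                seed=1000 + i,
            )
            series, _truth = generate_stack(config, GrowthParams())
            geom = detect_geometry(series.frames[0].astype(float))
            assert geom.n_channels == n_ch, f"scene {i}: {geom.n_channels} vs {n_ch}"
            for k, (left, _r) in enumerate(geom.channel_boxes):
                box_errors.append(abs(left - config.channel_left(k)))
        assert max(box_errors) <= 1

    def test_interval_invariant_under_illumination_and_scaling(self):
        config, frame, _t = _clean_scene(illumination_amplitude=0.0)
        g_plain = detect_geometry(frame)
        y, x = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        gradient = 0.08 * np.sin(np.pi * x / frame.shape[1])
        g_shaded = detect_geometry(2.0 * (frame + gradient))
        assert g_shaded.interval_px == pytest.approx(g_plain.interval_px, abs=1.0)


class TestFrameToFrame:
    def test_boxes_stable_across_registered_frames(self, small_scene):
        """Per-channel x positions vary < 1 px std across a drift-free run."""
        config = SceneConfig(
            n_channels=6, width_px=260, n_frames=10, seed=13, phase_px=28.0
        )
        series, _t = generate_stack(config, GrowthParams())
        canonical = detect_geometry(series.frames[0].astype(float))
        lefts = {k: [] for k in range(canonical.n_channels)}
        for f in range(series.n_frames):
            geom = detect_frame_boxes(series.frames[f].astype(float), canonical)
            mapping = match_channels(
                geom.channel_boxes, canonical.channel_boxes, canonical.interval_px
            )
            for box_idx, cid in mapping.items():
                lefts[cid].append(geom.channel_boxes[box_idx][0])
        for cid, xs in lefts.items():
            assert len(xs) == series.n_frames
            assert np.std(xs) < 1.0

    def test_match_channels_nearest_within_half_interval(self):
        reference = [(10, 20), (40, 50), (70, 80)]
        detected = [(11, 21), (69, 79), (200, 210)]
        mapping = match_channels(detected, reference, 30.0)
        assert mapping == {0: 0, 1: 2}


class TestGeometryInvariants:
    def test_geometry_type_validates(self):
        with pytest.raises(ValueError):
            ChannelGeometry(
                array_top=10, array_bottom=5, interval_px=30, width_px=10, phase_px=0
            )
        with pytest.raises(ValueError):
            ChannelGeometry(
                array_top=0, array_bottom=10, interval_px=30, width_px=10,
                phase_px=0, channel_boxes=[(0, 20)],  # width mismatch
            )
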