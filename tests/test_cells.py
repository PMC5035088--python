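"""1D cell detection: cleaned profiles, extrema, candidates, the three filters."""

import numpy as np
import pytest

from mmtrace.cells import (
    CellCandidate,
    DetectionParams,
    candidates_from_extrema,
    cleaned_profile,
    detect_cells,
    find_extrema,
    score_blackness,
    score_prominence,
)
from mmtrace.io_stack import Calibration
from mmtrace.synthetic import render_channel_crop

PX = 0.065
CAL = Calibration(pixel_size_um=PX, frame_interval_min=5.0)


def _random_channel(rng, n_cells=None, noise=0.05, height=230):
    """Random stacked cells (1.2-3.2 um) from the closed end; returns crop + truth."""
    n_cells = n_cells if n_cells is not None else int(rng.integers(1, 9))
    tops, cells = 6.0, []
    for _ in range(n_cells):
        length = rng.uniform(1.2, 3.2) / PX
        if tops + length > height - 30:
            break
        cells.append((tops, tops + length))
        tops += length
    crop = render_channel_crop(
        cells, height_px=height, noise_sigma=noise, rng=rng
    )
    return crop, cells


class TestCleanedProfile:
    def test_constant_crop_gives_zero(self):
        assert np.allclose(cleaned_profile(np.full((60, 10), 5.0)).values, 0.0)

    def test_linear_ramp_removed_cell_minima_remain(self):
        crop = render_channel_crop([(40.0, 70.0), (90.0, 120.0)], noise_sigma=0.0)
        ramp = np.linspace(0, 0.3, crop.shape[0])[:, None]
        cleaned = cleaned_profile(crop + ramp)
        v = cleaned.values
        assert v[50:60].mean() < v[15:25].mean()
        assert v[100:110].mean() < v[150:200].mean()

    def test_mean_near_zero(self, rng):
        crop, _ = _random_channel(rng)
        cleaned = cleaned_profile(crop)
        assert abs(cleaned.values.mean()) < 0.01 * np.ptp(cleaned.values)

    def test_tiny_crop_rejected(self):
        with pytest.raises(ValueError):
            cleaned_profile(np.zeros((4, 10)))


class TestFindExtrema:
    def test_sine_peaks_found_within_one_pixel(self):
        x = np.sin(2 * np.pi * np.arange(200) / 40.0)
        maxima, minima = find_extrema(x, window=11)
        expected = [10 + 40 * k for k in range(5)]
        # all five true peaks found within 1 px; anything extra is a
        # deliberate boundary extremum within half a window of the ends
        interior = [p for p in maxima if 5 <= p < 195]
        assert len(interior) == 5
        for found, true in zip(interior, expected):
            assert abs(found - true) <= 1
        assert all(p < 5 or p >= 195 for p in set(maxima) - set(interior))

    def test_monotone_profile_has_no_interior_extrema(self):
        maxima, minima = find_extrema(np.linspace(0, 1, 50), window=5)
        interior_max = [p for p in maxima if 2 < p < 47]
        interior_min = [p for p in minima if 2 < p < 47]
        assert not interior_max and not interior_min

    def test_plateau_collapses_to_centre(self):
        ramp = np.linspace(0, 1, 6)
        x = np.concatenate([ramp, np.ones(5), ramp[::-1]])  # plateau at 6..10
        maxima, _ = find_extrema(x, window=5)
        assert maxima == [8]

    def test_alternation_enforced(self, rng):
        x = np.cumsum(rng.normal(size=300))
        maxima, minima = find_extrema(x, window=5)
        events = sorted([(p, "M") for p in maxima] + [(p, "m") for p in minima])
        kinds = [k for _p, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_hysteresis_prunes_shallow_noise_pairs_in_dark_regions(self, rng):
        """Noise wiggles inside a deep valley (a cell interior) are pruned,
        so the valley yields no interior maxima that would split a cell."""
        x = np.zeros(200)
        x[50:150] = -1.0
        x = x + 0.01 * rng.normal(size=200)
        maxima, _ = find_extrema(x, window=5, min_delta=0.2)
        assert not [p for p in maxima if 55 < p < 145]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(np.zeros(10), window=4)


class TestCandidates:
    def test_adjacent_maxima_pairing(self):
        cands = candidates_from_extrema([10, 40, 80], PX)
        assert [(c.top_px, c.bottom_px) for c in cands] == [(10, 40), (40, 80)]
        assert cands[0].length_um == pytest.approx(30 * PX)

    def test_fewer_than_two_maxima_gives_nothing(self):
        assert candidates_from_extrema([17], PX) == []

    def test_candidate_type_validates(self):
        with pytest.raises(ValueError):
            CellCandidate(top_px=10, bottom_px=10, length_um=0.0)


class TestBlackness:
    def test_dark_region_scores_high_bright_scores_low(self):
        crop = render_channel_crop([(60.0, 120.0)], noise_sigma=0.02,
                                   rng=np.random.default_rng(0))
        dark = CellCandidate(top_px=65, bottom_px=115, length_um=1.0)
        bright = CellCandidate(top_px=150, bottom_px=210, length_um=1.0)
        assert score_blackness(dark, crop) > 0.9
        assert score_blackness(bright, crop) < 0.1

    def test_partial_coverage_tracks_fill_fraction(self):
        crop = render_channel_crop([(60.0, 100.0)], noise_sigma=0.02,
                                   rng=np.random.default_rng(1))
        # candidate box spans 50 px of which the cell occupies 40 (80 %)
        cand = CellCandidate(top_px=55, bottom_px=105, length_um=1.0)
        assert score_blackness(cand, crop) == pytest.approx(0.8, abs=0.05)

    def test_degenerate_crop_scores_zero(self):
        cand = CellCandidate(top_px=2, bottom_px=8, length_um=1.0)
        assert score_blackness(cand, np.full((20, 8), 3.0)) == 0.0


class TestProminence:
    def test_sine_prominence_is_twice_amplitude(self):
        amp = 0.7
        x = amp * np.sin(2 * np.pi * np.arange(400) / 50.0)
        maxima, minima = find_extrema(x, window=9)
        cand = CellCandidate(top_px=maxima[2], bottom_px=maxima[3], length_um=1.0)
        got = score_prominence(cand, x, maxima, minima)
        assert got == pytest.approx(2 * amp, rel=0.1)

    def test_flat_profile_with_jitter_has_negligible_prominence(self, rng):
        x = 0.001 * rng.normal(size=200)
        maxima, minima = find_extrema(x, window=5)
        if len(maxima) >= 2:
            cand = CellCandidate(
                top_px=maxima[0], bottom_px=maxima[1], length_um=1.0
            )
            assert score_prominence(cand, x, maxima, minima) < 0.02

    def test_deep_cell_dip_dominates_shallow_noise_dip(self):
        x = np.zeros(200)
        x[40:80] -= 1.0  # cell dip
        x[130:140] -= 0.05  # shallow noise dip
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(x, 3.0)
        maxima, minima = find_extrema(x, window=7)
        cands = candidates_from_extrema(maxima, PX)
        proms = {
            (c.top_px, c.bottom_px): score_prominence(c, x, maxima, minima)
            for c in cands
        }
        cell_prom = max(v for (t, b), v in proms.items() if t < 60 < b)
        noise_prom = min(v for (t, b), v in proms.items() if t > 100)
        assert cell_prom > 5 * noise_prom


class TestDetectCells:
    def test_debris_rejected_by_length_filter(self):
        """Four cells plus 0.5 um debris: the debris fails the 1 um filter."""
        cells = [(6, 40), (40, 72), (72, 110), (110, 150)]
        debris = (165, 165 + 0.5 / PX)  # ~8 px
        crop = render_channel_crop(
            [(float(a), float(b)) for a, b in cells] + [debris],
            noise_sigma=0.03, rng=np.random.default_rng(5),
        )
        accepted = detect_cells(crop, DetectionParams(), CAL)
        assert len(accepted) == 4
        assert all(c.length_um >= 1.0 for c in accepted)

    def test_bright_gap_candidate_rejected_by_blackness(self):
        """A candidate spanning the bright gap between distant cells fails
        the 50 % blackness criterion."""
        crop = render_channel_crop(
            [(20.0, 60.0), (140.0, 180.0)], noise_sigma=0.03,
            rng=np.random.default_rng(6),
        )
        accepted = detect_cells(crop, DetectionParams(), CAL)
        assert len(accepted) == 2
        for cand in accepted:
            assert cand.blackness >= 0.5
            assert not (60 < cand.center_px < 140)

    def test_empty_channel_gives_empty_list(self):
        crop = render_channel_crop([], noise_sigma=0.03,
                                   rng=np.random.default_rng(7))
        assert detect_cells(crop, DetectionParams(), CAL) == []

    def test_accepted_cells_never_overlap(self, rng):
        for _ in range(20):
            crop, _ = _random_channel(rng)
            accepted = detect_cells(crop, DetectionParams(), CAL)
            for a, b in zip(accepted, accepted[1:]):
                assert a.bottom_px <= b.top_px

    def test_invariant_under_affine_intensity_rescale(self, rng):
        crop, _ = _random_channel(rng, n_cells=4)
        base = detect_cells(crop, DetectionParams(), CAL)
        scaled = detect_cells(crop * 37.0 + 11.0, DetectionParams(), CAL)
        assert [(c.top_px, c.bottom_px) for c in base] == [
            (c.top_px, c.bottom_px) for c in scaled
        ]

    def test_random_channels_count_accuracy_and_boundary_error(self):
        """>= 95 % exact counts and <= 2 px boundary MAE over 200 random
        channels with 1-8 cells at SNR >= 3."""
        rng = np.random.default_rng(77)
        exact = 0
        errors = []
        n_scenes = 200
        for _ in range(n_scenes):
            noise = float(rng.uniform(0.02, 0.14))  # dip 0.43 -> SNR >= 3
            crop, cells = _random_channel(rng, noise=noise)
            accepted = detect_cells(crop, DetectionParams(), CAL)
            if len(accepted) == len(cells):
                exact += 1
                for (t, b), cand in zip(cells, accepted):
                    errors += [abs(t - cand.top_px), abs(b - cand.bottom_px)]
        assert exact / n_scenes >= 0.95
        assert np.mean(errors) <= 2.0
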