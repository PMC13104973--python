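"""Ruffling-rate pipeline: rolling-median baseline, percent-ratio
normalization, multi-scale adaptive ruffle segmentation, cell
segmentation and the per-video rate."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bampquant import synthetic as syn
from bampquant.ruffle import (
    RatioMovie,
    RuffleParams,
    ratio_normalize,
    ruffling_rate,
    ruffling_rate_pipeline,
    segment_cells,
    segment_ruffles,
    temporal_baseline,
)
from bampquant.types import MaskStack, Movie


def brute_force_median(data: np.ndarray, h: int) -> np.ndarray:
    """Independent oracle: per-pixel sorted-window median, truncated at
    the movie ends."""
    T = data.shape[0]
    out = np.empty_like(data)
    for t in range(T):
        window = data[max(0, t - h): min(T, t + h + 1)]
        out[t] = np.sort(window, axis=0)[window.shape[0] // 2] if window.shape[0] % 2 else \
            0.5 * (np.sort(window, axis=0)[window.shape[0] // 2 - 1]
                   + np.sort(window, axis=0)[window.shape[0] // 2])
    return out


class TestTemporalBaseline:
    def test_constant_movie_unchanged(self):
        movie = Movie(np.full((9, 8, 8), 7.0))
        base = temporal_baseline(movie, RuffleParams(half_window_frames=3))
        np.testing.assert_array_equal(base.data, 7.0)

    def test_spike_suppressed(self):
        series = np.array([1, 1, 1, 100, 1, 1, 1], dtype=float)
        movie = Movie(series[:, None, None])
        base = temporal_baseline(movie, RuffleParams(half_window_frames=3))
        assert base.data[3, 0, 0] == 1.0

    @pytest.mark.parametrize("h", [1, 2, 5])
    def test_matches_brute_force_oracle(self, h):
        rng = np.random.default_rng(42 + h)
        data = rng.uniform(0, 100, size=(15, 6, 7))
        base = temporal_baseline(Movie(data), RuffleParams(half_window_frames=h))
        np.testing.assert_array_equal(base.data, brute_force_median(data, h))


class TestRatioNormalize:
    def test_identity_gives_100(self):
        data = np.full((4, 5, 5), 30.0)
        ratio = ratio_normalize(Movie(data), Movie(data), RuffleParams(ratio_floor=0.0))
        np.testing.assert_allclose(ratio.data, 100.0)

    def test_doubling_gives_200(self):
        base = np.full((3, 4, 4), 10.0)
        ratio = ratio_normalize(Movie(2 * base), Movie(base), RuffleParams(ratio_floor=0.0))
        np.testing.assert_allclose(ratio.data, 200.0)

    def test_zero_baseline_flagged(self):
        raw = np.full((2, 3, 3), 5.0)
        base = np.zeros((2, 3, 3))
        ratio = ratio_normalize(Movie(raw), Movie(base), RuffleParams(ratio_floor=1.0))
        assert ratio.background_flag.all()
        np.testing.assert_array_equal(ratio.data, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ratio_normalize(Movie(np.ones((2, 3, 3))), Movie(np.ones((2, 4, 4))))

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_intensity_scale_invariance(self, c):
        """Multiplying raw and baseline by the same constant leaves the
        percent ratio unchanged where unflagged."""
        rng = np.random.default_rng(7)
        raw = rng.uniform(10, 100, (4, 6, 6))
        base = rng.uniform(10, 100, (4, 6, 6))
        p = RuffleParams(ratio_floor=1.0)
        r1 = ratio_normalize(Movie(raw), Movie(base), p)
        p2 = RuffleParams(ratio_floor=1.0 * c)
        r2 = ratio_normalize(Movie(c * raw), Movie(c * base), p2)
        np.testing.assert_allclose(r1.data, r2.data, rtol=1e-9)


class TestSegmentRuffles:
    def test_uniform_ratio_gives_empty_masks(self):
        ratio = RatioMovie(np.full((3, 64, 64), 100.0), np.zeros((3, 64, 64), bool))
        masks = segment_ruffles(ratio)
        assert not masks.masks.any()

    def test_planted_block_recovered(self):
        frame = np.full((100, 100), 100.0)
        frame[40:60, 40:60] = 300.0
        ratio = RatioMovie(frame[None], np.zeros((1, 100, 100), bool))
        mask = segment_ruffles(ratio).masks[0]
        truth = np.zeros((100, 100), bool)
        truth[40:60, 40:60] = True
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.8

    def test_narrow_and_wide_regions_both_detected(self):
        from scipy import ndimage
        frame = np.full((100, 100), 100.0)
        frame[20:50, 10:14] = 300.0   # 4 px wide
        frame[60:80, 40:60] = 300.0   # 20 px wide
        ratio = RatioMovie(frame[None], np.zeros((1, 100, 100), bool))
        mask = segment_ruffles(ratio).masks[0]
        t1 = np.zeros((100, 100), bool); t1[20:50, 10:14] = True
        t2 = np.zeros((100, 100), bool); t2[60:80, 40:60] = True
        labels, n = ndimage.label(mask)
        assert n >= 2
        assert np.unique(labels[t1 & mask]).size >= 1 and (t1 & mask).any()
        assert (t2 & mask).any()

    def test_background_flag_never_segmented(self):
        frame = np.full((1, 64, 64), 300.0)
        flag = np.zeros((1, 64, 64), bool)
        flag[0, :32] = True
        masks = segment_ruffles(RatioMovie(frame, flag))
        assert not masks.masks[0, :32].any()


class TestSegmentCells:
    def test_synthetic_ellipse_recovered(self):
        scene = syn.SceneSpec(n_frames=3, noise_sd=2.0, seed=5)
        movie, gt = syn.generate_ruffle_movie(scene)
        cells = segment_cells(movie)
        for t in range(3):
            inter = (cells.masks[t] & gt.cell_masks[t]).sum()
            union = (cells.masks[t] | gt.cell_masks[t]).sum()
            assert inter / union >= 0.95

    def test_blank_movie_warns_and_empty(self):
        rng = np.random.default_rng(0)
        movie = Movie(rng.normal(10, 1, size=(2, 64, 64)).clip(0))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(UserWarning):
                segment_cells(movie)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cells = segment_cells(movie)
        assert not cells.masks.any()

    def test_two_cells_two_components(self):
        from scipy import ndimage
        frame = np.full((100, 200), 10.0)
        rr, cc = np.ogrid[:100, :200]
        frame[((rr - 50) / 25) ** 2 + ((cc - 50) / 25) ** 2 <= 1] = 200.0
        frame[((rr - 50) / 25) ** 2 + ((cc - 150) / 25) ** 2 <= 1] = 200.0
        cells = segment_cells(Movie(frame[None]))
        _, n = ndimage.label(cells.masks[0])
        assert n == 2


class TestRufflingRate:
    def test_simple_arithmetic(self):
        cell = np.zeros((2, 20, 20), bool)
        cell[:, :10, :10] = True  # 100 px
        ruf = np.zeros_like(cell)
        ruf[:, :2, :5] = True  # 10 px
        res = ruffling_rate(MaskStack(ruf, "ruffle"), MaskStack(cell, "cell"))
        np.testing.assert_allclose(res.per_frame_percent, 10.0)
        assert res.mean_rate_percent == pytest.approx(10.0)

    def test_empty_ruffles_zero_rate(self):
        cell = np.ones((3, 8, 8), bool)
        res = ruffling_rate(MaskStack(np.zeros_like(cell), "ruffle"), MaskStack(cell, "cell"))
        assert res.mean_rate_percent == 0.0

    def test_empty_cell_frames_excluded(self):
        cell = np.ones((3, 8, 8), bool)
        cell[1] = False
        ruf = np.zeros_like(cell)
        ruf[:, :2, :4] = True
        res = ruffling_rate(MaskStack(ruf, "ruffle"), MaskStack(cell, "cell"))
        assert res.excluded_frames == [1]
        assert np.isnan(res.per_frame_percent[1])
        assert res.mean_rate_percent == pytest.approx(100 * 8 / 64)

    def test_all_empty_cell_masks_rejected(self):
        empty = np.zeros((2, 4, 4), bool)
        with pytest.raises(ValueError, match="empty cell mask"):
            ruffling_rate(MaskStack(empty, "ruffle"), MaskStack(empty, "cell"))

    def test_scores_within_range(self, small_ruffle_scene):
        scene, events = small_ruffle_scene
        movie, _ = syn.generate_ruffle_movie(scene, events)
        res = ruffling_rate_pipeline(movie)
        valid = res.per_frame_percent[~np.isnan(res.per_frame_percent)]
        assert np.all((valid >= 0) & (valid <= 100))


class TestEndToEnd:
    def test_recovery_of_planted_fraction(self, small_ruffle_scene):
        scene, events = small_ruffle_scene
        rng = np.random.default_rng(1)
        events = syn.plan_ruffle_events(0.08, scene.n_frames, rng)
        movie, gt = syn.generate_ruffle_movie(scene, events)
        planted = 100 * (gt.ruffle_masks.sum(axis=(1, 2))
                         / gt.cell_masks.sum(axis=(1, 2))).mean()
        res = ruffling_rate_pipeline(movie)
        assert res.mean_rate_percent == pytest.approx(planted, abs=2.0)

    def test_monotone_in_planted_fraction(self):
        rates = []
        for frac in (0.03, 0.08, 0.15):
            rng = np.random.default_rng(17)
            scene = syn.SceneSpec(n_frames=40, seed=17)
            movie, _ = syn.generate_ruffle_movie(
                scene, syn.plan_ruffle_events(frac, 40, rng))
            rates.append(ruffling_rate_pipeline(movie).mean_rate_percent)
        assert rates[0] < rates[1] < rates[2]

    def test_whole_movie_scale_invariance(self, small_ruffle_scene):
        scene, events = small_ruffle_scene
        movie, _ = syn.generate_ruffle_movie(scene, events)
        r1 = ruffling_rate_pipeline(movie)
        r2 = ruffling_rate_pipeline(Movie(movie.data * 3.5))
        assert r2.mean_rate_percent == pytest.approx(r1.mean_rate_percent, abs=1e-9)
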