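"""Ruffling-rate quantification for actin live-cell movies.

Membrane ruffles move fast, unlike stress fibers, so they register as
transient spikes in per-pixel intensity time courses. The pipeline:

1. :func:`temporal_baseline` — per-pixel rolling temporal median
   (default ±25 frames, i.e. ±50 s at a 2 s frame interval) extracts the
   low-frequency actin image.
2. :func:`ratio_normalize` — raw / baseline on a percentage scale
   highlights high-temporal-frequency regions; static structures sit at
   100%.
3. :func:`segment_ruffles` — multi-scale locally adaptive thresholding of
   the ratio movie delineates ruffling areas per frame.
4. :func:`segment_cells` — the whole cell is segmented separately in the
   raw actin image.
5. :func:`ruffling_rate` — ruffle area as a percentage of cell area per
   frame, averaged over time, is the per-video ruffling rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects

from .types import MaskStack, Movie

__all__ = [
    "RuffleParams",
    "RatioMovie",
    "RuffleRateResult",
    "temporal_baseline",
    "ratio_normalize",
    "segment_ruffles",
    "segment_cells",
    "ruffling_rate",
    "ruffling_rate_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RuffleParams:
    """Tunable parameters of the ruffling-rate pipeline.

    ``half_window_frames=25`` corresponds to the ±50 s rolling window at a
    2 s frame interval. ``ratio_floor=None`` resolves at run time to 10% of
    the movie's median foreground intensity; baseline values below the
    floor are treated as background and excluded from the ratio movie.
    ``min_excess_percent`` is a global floor on the percent-ratio a pixel
    must exceed to count as a ruffle candidate (static scenes sit at 100%).
    """

    half_window_frames: int = 25
    ratio_floor: Optional[float] = None
    scale_sigmas: Sequence[float] = (1.0, 2.0, 4.0)
    min_object_px: int = 20
    restrict_to_cell: bool = True
    min_excess_percent: float = 130.0
    tile_px: int = 32
    min_tile_contrast: float = 0.5
    cell_smooth_sigma: float = 2.0
    cell_threshold: Optional[float] = None
    min_cell_contrast: float = 2.0

    def __post_init__(self) -> None:
        if self.half_window_frames < 1:
            raise ValueError("half_window_frames must be >= 1")
        sig = list(self.scale_sigmas)
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("scale_sigmas must be strictly increasing")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")

    @property
    def n_scales(self) -> int:
        return len(list(self.scale_sigmas))


@dataclass
class RatioMovie:
    """Percent-scale ratio of raw to baseline intensities.

    ``background_flag`` marks pixels whose baseline fell under the ratio
    floor; those carry value 0 and are never segmented as ruffles.
    """

    data: np.ndarray
    background_flag: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.background_flag = np.asarray(self.background_flag, dtype=bool)
        if self.data.shape != self.background_flag.shape:
            raise ValueError("data and background_flag shapes differ")


@dataclass
class RuffleRateResult:
    """Per-frame ruffle-area percentages and their temporal mean.

    ``per_frame_percent`` is NaN for frames whose cell mask was empty;
    those frames are listed in ``excluded_frames`` and do not enter
    ``mean_rate_percent``.
    """

    per_frame_percent: np.ndarray
    mean_rate_percent: float
    excluded_frames: list[int] = field(default_factory=list)
    params_used: Optional[RuffleParams] = None


def temporal_baseline(movie: Movie, params: RuffleParams | None = None) -> Movie:
    """Per-pixel rolling temporal median over ±``half_window_frames``.

    The window truncates at the movie ends (the median is taken over the
    available frames), so the baseline stays an order statistic of real
    data rather than of reflected copies.
    """
    params = params or RuffleParams()
    data = movie.data
    T = data.shape[0]
    h = params.half_window_frames
    out = np.empty_like(data)
    for t in range(T):
        lo, hi = max(0, t - h), min(T, t + h + 1)
        out[t] = np.median(data[lo:hi], axis=0)
    return Movie(out, frame_interval=movie.frame_interval, pixel_size=movie.pixel_size)


def default_ratio_floor(movie: Movie) -> float:
    """10% of the movie's median foreground intensity.

    Foreground is taken as pixels above the global Otsu threshold of the
    movie; if the movie is constant the overall median is used.
    """
    data = movie.data
    if np.ptp(data) == 0:
        return 0.1 * float(np.median(data))
    thr = threshold_otsu(data)
    fg = data[data > thr]
    ref = np.median(fg) if fg.size else np.median(data)
    return 0.1 * float(ref)


def ratio_normalize(
    movie: Movie, baseline: Movie, params: RuffleParams | None = None
) -> RatioMovie:
    """Raw / baseline on a percentage scale (static signal → 100).

    Pixels whose baseline falls below the ratio floor are flagged as
    background and set to 0, guarding the division against near-zero
    baselines.
    """
    params = params or RuffleParams()
    if movie.data.shape != baseline.data.shape:
        raise ValueError("movie and baseline shapes differ")
    floor = params.ratio_floor
    if floor is None:
        floor = default_ratio_floor(movie)
    flag = baseline.data < floor
    ratio = np.zeros_like(movie.data)
    np.divide(movie.data, baseline.data, out=ratio, where=~flag)
    ratio *= 100.0
    ratio[flag] = 0.0
    return RatioMovie(ratio, flag)


def _tile_adaptive_threshold(
    frame: np.ndarray, valid: np.ndarray, params: RuffleParams
) -> np.ndarray:
    """Locally adaptive threshold map via per-tile Otsu with a contrast gate.

    Tiles where Otsu separates a genuinely brighter class (relative mean
    contrast at least ``min_tile_contrast``) use their local Otsu
    threshold; all other tiles — constant tiles (e.g. the interior of a
    large ruffle) and tiles without a bright class — fall back to the
    global ``min_excess_percent`` floor, which is also the lower bound on
    every local threshold.
    """
    h, w = frame.shape
    tp = params.tile_px
    thresh = np.full(frame.shape, params.min_excess_percent)
    for r0 in range(0, h, tp):
        for c0 in range(0, w, tp):
            sl = (slice(r0, min(r0 + tp, h)), slice(c0, min(c0 + tp, w)))
            vals = frame[sl][valid[sl]]
            if vals.size < 16 or np.ptp(vals) == 0:
                continue
            t = threshold_otsu(vals)
            above = vals[vals > t]
            below = vals[vals <= t]
            if above.size == 0 or below.size == 0:
                continue
            mb = below.mean()
            if mb <= 0 or (above.mean() - mb) / mb < params.min_tile_contrast:
                continue
            thresh[sl] = t
    return np.maximum(thresh, params.min_excess_percent)


def segment_ruffles(ratio: RatioMovie, params: RuffleParams | None = None) -> MaskStack:
    """Multi-scale locally adaptive segmentation of high-ratio regions.

    Each frame is smoothed at every scale in ``scale_sigmas``; each
    smoothed image is thresholded by a tile-based local Otsu (gated by
    contrast and by the global percent floor); the per-scale masks are
    unioned and objects smaller than ``min_object_px`` removed. Flagged
    background pixels are never included.
    """
    params = params or RuffleParams()
    T = ratio.data.shape[0]
    masks = np.zeros(ratio.data.shape, dtype=bool)
    for t in range(T):
        frame = ratio.data[t]
        valid = ~ratio.background_flag[t]
        acc = np.zeros(frame.shape, dtype=bool)
        for sigma in params.scale_sigmas:
            sm = gaussian(frame, sigma=sigma, preserve_range=True)
            thr = _tile_adaptive_threshold(sm, valid, params)
            acc |= (sm > thr) & valid
        if params.min_object_px > 0:
            acc = remove_small_objects(acc, max_size=params.min_object_px - 1)
        masks[t] = acc
    return MaskStack(masks, role="ruffle")


def segment_cells(movie: Movie, params: RuffleParams | None = None) -> MaskStack:
    """Per-frame whole-cell segmentation of the raw actin movie.

    Global Otsu on a spatially smoothed frame, hole filling, size filter.
    A frame whose Otsu foreground is not at least ``min_cell_contrast``
    times brighter than its background is declared empty (with a warning):
    Otsu always splits a histogram, even of pure noise, so the contrast
    gate is what distinguishes "no cell in this frame" from a real cell.
    A fixed ``cell_threshold`` bypasses Otsu entirely.
    """
    params = params or RuffleParams()
    T = movie.data.shape[0]
    masks = np.zeros(movie.data.shape, dtype=bool)
    for t in range(T):
        frame = gaussian(movie.data[t], sigma=params.cell_smooth_sigma, preserve_range=True)
        if params.cell_threshold is not None:
            fg = frame >= params.cell_threshold
        else:
            if np.ptp(frame) == 0:
                fg = np.zeros(frame.shape, dtype=bool)
            else:
                thr = threshold_otsu(frame)
                fg = frame > thr
                if fg.any() and not fg.all():
                    mfg, mbg = frame[fg].mean(), frame[~fg].mean()
                    if mbg <= 0 or mfg / max(mbg, 1e-12) < params.min_cell_contrast:
                        fg = np.zeros(frame.shape, dtype=bool)
        fg = ndimage.binary_fill_holes(fg)
        if params.min_object_px > 0:
            fg = remove_small_objects(fg, max_size=params.min_object_px - 1)
        if not fg.any():
            warnings.warn(f"no cell foreground found in frame {t}", stacklevel=2)
            logger.warning("segment_cells: empty mask at frame %d", t)
        masks[t] = fg
    return MaskStack(masks, role="cell")


def ruffling_rate(
    ruffles: MaskStack, cells: MaskStack, params: RuffleParams | None = None
) -> RuffleRateResult:
    """Ruffle area as a percentage of cell area, per frame and time-averaged.

    Frames with an empty cell mask are excluded from the mean (NaN in the
    per-frame trace) rather than scored zero, so segmentation failures do
    not dilute the rate.
    """
    params = params or RuffleParams()
    if ruffles.shape != cells.shape:
        raise ValueError("ruffle and cell mask stacks must have equal shapes")
    T = ruffles.shape[0]
    per_frame = np.full(T, np.nan)
    excluded: list[int] = []
    for t in range(T):
        cell = cells.masks[t]
        n_cell = int(cell.sum())
        if n_cell == 0:
            excluded.append(t)
            continue
        ruf = ruffles.masks[t]
        if params.restrict_to_cell:
            ruf = ruf & cell
        per_frame[t] = 100.0 * ruf.sum() / n_cell
    if len(excluded) == T:
        raise ValueError("every frame has an empty cell mask; cannot compute a ruffling rate")
    mean_rate = float(np.nanmean(per_frame))
    return RuffleRateResult(per_frame, mean_rate, excluded, params)


def ruffling_rate_pipeline(movie: Movie, params: RuffleParams | None = None) -> RuffleRateResult:
    """Full pipeline: baseline → ratio → ruffle + cell segmentation → rate."""
    params = params or RuffleParams()
    baseline = temporal_baseline(movie, params)
    ratio = ratio_normalize(movie, baseline, params)
    ruffles = segment_ruffles(ratio, params)
    cells = segment_cells(movie, params)
    return ruffling_rate(ruffles, cells, params)
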