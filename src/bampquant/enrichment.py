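"""Subcellular-enrichment quantification for two-channel protrusion movies.

A membrane-bound reporter (e.g. a tagged KRAS) imaged alongside a uniform
membrane marker: dividing reporter by marker cancels membrane-fold
geometry, leaving a per-pixel relative concentration. Cells are segmented
at a user-tuned threshold at a baseline frame T0 and at the frame of
maximal protrusion T1; pixels in the cell at T1 but not T0 are the
protrusive class, pixels present at both times the non-protrusive class,
and enrichment is the ratio of mean normalized reporter intensity between
the two classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

from .types import Movie

__all__ = [
    "EnrichmentParams",
    "NormalizedMovie",
    "ProtrusionPartition",
    "EnrichmentResult",
    "normalize_by_membrane",
    "segment_cell_frame",
    "partition_protrusions",
    "enrichment_stats",
    "enrichment_pipeline",
    "suggest_t1",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentParams:
    """User-set parameters of the enrichment analysis.

    ``seg_threshold`` is the manually tuned intensity threshold separating
    individual cells from background (applied to the membrane-marker
    channel by default). ``t0_frame`` is the first light-activation frame
    and ``t1_frame`` the user-assessed frame of maximal protrusion.
    ``membrane_floor`` excludes pixels whose membrane signal is too weak
    for the ratio to be meaningful. ``average_frames`` switches the
    statistics from the T1 frame only to the mean over T0..T1.
    """

    seg_threshold: float
    t0_frame: int = 0
    t1_frame: int = -1
    membrane_floor: float = 0.0
    min_object_px: int = 0
    average_frames: bool = False
    seg_channel: str = "membrane"

    def __post_init__(self) -> None:
        if self.seg_threshold <= 0:
            raise ValueError("seg_threshold must be > 0")
        if self.seg_channel not in ("membrane", "reporter"):
            raise ValueError("seg_channel must be 'membrane' or 'reporter'")

    def resolve_frames(self, n_frames: int) -> tuple[int, int]:
        t0 = self.t0_frame % n_frames
        t1 = self.t1_frame % n_frames
        if not t0 < t1:
            raise ValueError(f"need t0_frame < t1_frame, got {t0} >= {t1}")
        return t0, t1


@dataclass
class NormalizedMovie:
    """Reporter/membrane ratio movie; excluded pixels (weak membrane
    signal) carry value 0 and ``excluded_flag`` True."""

    data: np.ndarray
    excluded_flag: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.excluded_flag = np.asarray(self.excluded_flag, dtype=bool)
        if self.data.shape != self.excluded_flag.shape:
            raise ValueError("data and excluded_flag shapes differ")


@dataclass
class ProtrusionPartition:
    """Protrusive vs non-protrusive pixel classes derived from the T0/T1
    cell masks: protrusive = T1 and not T0; non-protrusive = T0 and T1.
    Pixels present only at T0 (retraction) belong to neither class."""

    mask_t0: np.ndarray
    mask_t1: np.ndarray
    protrusive: np.ndarray
    non_protrusive: np.ndarray

    def __post_init__(self) -> None:
        assert not np.any(self.protrusive & self.non_protrusive), "classes must be disjoint"
        assert not np.any(self.protrusive & ~self.mask_t1), "protrusive must lie within T1 mask"
        assert not np.any(self.non_protrusive & ~self.mask_t1), "non-protrusive must lie within T1 mask"


@dataclass
class EnrichmentResult:
    mean_protrusive: float
    mean_non_protrusive: float
    enrichment_ratio: float
    n_px_protrusive: int
    n_px_non_protrusive: int


def normalize_by_membrane(
    reporter: Movie, membrane: Movie, params: EnrichmentParams
) -> NormalizedMovie:
    """Divide each reporter frame by the matching membrane-marker frame.

    Pixels with membrane signal below ``membrane_floor`` are excluded
    (value 0, flag set) rather than divided.
    """
    if reporter.data.shape != membrane.data.shape:
        raise ValueError("reporter and membrane movies must have equal shapes")
    flag = membrane.data < params.membrane_floor
    out = np.zeros_like(reporter.data)
    np.divide(reporter.data, membrane.data, out=out, where=~flag & (membrane.data != 0))
    out[flag] = 0.0
    return NormalizedMovie(out, flag)


def segment_cell_frame(frame: np.ndarray, params: EnrichmentParams) -> np.ndarray:
    """Foreground/background segmentation of one frame at the tuned
    threshold, with hole filling and size filtering."""
    frame = np.asarray(frame, dtype=np.float64)
    mask = frame >= params.seg_threshold
    mask = ndimage.binary_fill_holes(mask)
    if params.min_object_px > 0:
        mask = remove_small_objects(mask, max_size=params.min_object_px - 1)
    if not mask.any():
        warnings.warn("cell segmentation produced an empty mask", stacklevel=2)
    return mask


def partition_protrusions(mask_t0: np.ndarray, mask_t1: np.ndarray) -> ProtrusionPartition:
    """Set-difference partition of the T1 cell into protrusive and
    non-protrusive pixel classes."""
    mask_t0 = np.asarray(mask_t0, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t0.shape != mask_t1.shape:
        raise ValueError("masks must have equal shapes")
    protrusive = mask_t1 & ~mask_t0
    non_protrusive = mask_t0 & mask_t1
    return ProtrusionPartition(mask_t0, mask_t1, protrusive, non_protrusive)


def enrichment_stats(
    normalized: NormalizedMovie,
    partition: ProtrusionPartition,
    params: EnrichmentParams,
) -> EnrichmentResult:
    """Mean normalized reporter intensity inside vs outside protrusions.

    Statistics are taken over the normalized T1 frame (or, with
    ``average_frames``, the mean of frames T0..T1), restricted to each
    class and to non-excluded pixels. The enrichment ratio is
    protrusive / non-protrusive; a class with no usable pixels yields NaN
    for its mean and the ratio, with a warning.
    """
    t0, t1 = params.resolve_frames(normalized.data.shape[0])
    if params.average_frames:
        sel = slice(t0, t1 + 1)
        excl = normalized.excluded_flag[sel].any(axis=0)
        frame = np.where(
            normalized.excluded_flag[sel], np.nan, normalized.data[sel]
        )
        frame = np.nanmean(frame, axis=0)
        frame = np.where(np.isnan(frame), 0.0, frame)
        excl = normalized.excluded_flag[sel].all(axis=0)
    else:
        frame = normalized.data[t1]
        excl = normalized.excluded_flag[t1]

    def class_mean(mask: np.ndarray) -> tuple[float, int]:
        usable = mask & ~excl
        n = int(usable.sum())
        if n == 0:
            warnings.warn("a partition class has no usable pixels", stacklevel=3)
            return float("nan"), 0
        return float(frame[usable].mean()), n

    mp, npx = class_mean(partition.protrusive)
    mn, nnx = class_mean(partition.non_protrusive)
    ratio = mp / mn if (npx and nnx and mn > 0) else float("nan")
    return EnrichmentResult(mp, mn, ratio, npx, nnx)


def suggest_t1(membrane: Movie, params: EnrichmentParams) -> int:
    """Suggest T1 as the frame maximizing newly protruded area relative to
    the T0 mask (helper; the final choice is the user's)."""
    t0 = params.t0_frame % membrane.n_frames
    m0 = segment_cell_frame(membrane.data[t0], params)
    best_t, best_area = t0 + 1, -1
    for t in range(t0 + 1, membrane.n_frames):
        mt = segment_cell_frame(membrane.data[t], params)
        area = int((mt & ~m0).sum())
        if area > best_area:
            best_t, best_area = t, area
    return best_t


def enrichment_pipeline(
    reporter: Movie, membrane: Movie, params: EnrichmentParams
) -> tuple[EnrichmentResult, ProtrusionPartition, NormalizedMovie]:
    """Full analysis: normalize, segment at T0/T1 (on the membrane channel
    by default; ``seg_channel='reporter'`` switches), partition, and
    compute the class means and enrichment ratio."""
    t0, t1 = params.resolve_frames(membrane.n_frames)
    normalized = normalize_by_membrane(reporter, membrane, params)
    seg_movie = membrane if params.seg_channel == "membrane" else reporter
    mask_t0 = segment_cell_frame(seg_movie.data[t0], params)
    mask_t1 = segment_cell_frame(seg_movie.data[t1], params)
    partition = partition_protrusions(mask_t0, mask_t1)
    result = enrichment_stats(normalized, partition, params)
    return result, partition, normalized
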