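"""Scalar assay readouts: EdU proliferation, integrated density, blot
densitometry.

These are deliberately simple, auditable formulas:

* proliferation rate — EdU-positive pixel count over DAPI-positive pixel
  count, as a percentage, with one shared threshold per compared group;
* integrated density — sum projection over z, then the total projected
  intensity inside a region of interest;
* relative blot density — band density normalized both to the solvent
  control lane and to the loading-control band;
* lane profile density — ImageJ-Gels-style band integration of a 1D lane
  profile above a straight-line baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelPair",
    "LaneMeasurement",
    "proliferation_rate",
    "integrated_density",
    "relative_density",
    "lane_profile_density",
    "suggest_threshold",
]


@dataclass
class ChannelPair:
    """Paired EdU and DAPI images with the shared absolute thresholds used
    for every sample in a comparison group."""

    edu: np.ndarray
    dapi: np.ndarray
    threshold_edu: float
    threshold_dapi: float

    def __post_init__(self) -> None:
        self.edu = np.asarray(self.edu, dtype=np.float64)
        self.dapi = np.asarray(self.dapi, dtype=np.float64)
        if self.edu.shape != self.dapi.shape:
            raise ValueError("EdU and DAPI images must have equal shapes")
        if self.threshold_edu <= 0 or self.threshold_dapi <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class LaneMeasurement:
    """One blot lane: the band of interest and its loading-control band."""

    band_density: float
    loading_density: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.band_density < 0 or self.loading_density < 0:
            raise ValueError("densities must be >= 0")


def proliferation_rate(pair: ChannelPair) -> float:
    """EdU-positive pixels over DAPI-positive pixels, in percent.

    The readout is pixel-based, not nucleus-count-based: the S-phase
    fraction is proxied by labeled nuclear area.
    """
    n_edu = int(np.count_nonzero(pair.edu >= pair.threshold_edu))
    n_dapi = int(np.count_nonzero(pair.dapi >= pair.threshold_dapi))
    if n_dapi == 0:
        raise ValueError("no DAPI-positive pixels; cannot form a proliferation ratio")
    return 100.0 * n_edu / n_dapi


def integrated_density(stack: np.ndarray, roi_mask: np.ndarray) -> float:
    """Total fluorescence inside an ROI on the sum projection of a stack.

    ``stack`` may be 2D (a single plane) or 3D (summed over the leading
    axis first); ``roi_mask`` is a 2D boolean region of interest.
    """
    stack = np.asarray(stack, dtype=np.float64)
    roi = np.asarray(roi_mask, dtype=bool)
    if stack.ndim == 3:
        proj = stack.sum(axis=0)
    elif stack.ndim == 2:
        proj = stack
    else:
        raise ValueError("stack must be 2D or 3D")
    if proj.shape != roi.shape:
        raise ValueError("ROI shape must match the projected image")
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(proj[roi].sum())


def relative_density(sample: LaneMeasurement, solvent_control: LaneMeasurement) -> float:
    """Band density normalized to the solvent-control lane and to the
    loading-control bands:
    ``(sample.band / control.band) / (sample.loading / control.loading)``.
    """
    if min(
        sample.band_density,
        sample.loading_density,
        solvent_control.band_density,
        solvent_control.loading_density,
    ) <= 0:
        raise ValueError("all four densities must be > 0")
    return (sample.band_density / solvent_control.band_density) / (
        sample.loading_density / solvent_control.loading_density
    )


def lane_profile_density(profile: np.ndarray, band_window: tuple[int, int]) -> float:
    """Integrated band density of a 1D lane profile.

    A straight-line baseline is drawn between the profile values at the
    window endpoints and subtracted; the baseline-corrected profile is
    integrated over the window (trapezoid rule, unit sample spacing) and
    clipped at zero. This mirrors the manual lane-plot convention of gel
    analysis tools.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    start, end = band_window
    if not (0 <= start < end < profile.size):
        raise ValueError(
            f"band window ({start}, {end}) degenerate or outside profile of length {profile.size}"
        )
    window = profile[start : end + 1]
    baseline = np.linspace(window[0], window[-1], window.size)
    corrected = window - baseline
    return max(float(np.trapezoid(corrected)), 0.0)


def suggest_threshold(image: np.ndarray) -> float:
    """Otsu-based threshold suggestion for an EdU or DAPI channel; the
    chosen threshold must then be shared across all compared samples."""
    image = np.asarray(image, dtype=np.float64)
    if np.ptp(image) == 0:
        raise ValueError("constant image has no meaningful threshold")
    return float(threshold_otsu(image))
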