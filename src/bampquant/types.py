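"""Core in-memory containers shared by all pipelines.

Axis conventions are fixed package-wide: movies are ``T x Y x X``, volumes
are ``Z x Y x X``, coordinates are 0-based integer voxel indices, and masks
are boolean arrays aligned to their source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Movie", "Volume", "MaskStack", "SpotList", "CellMask3D"]


@dataclass
class Movie:
    """A single-channel time-lapse movie.

    Parameters
    ----------
    data
        ``T x Y x X`` array of nonnegative intensities in arbitrary units.
        Integer input is promoted to float64 without changing values.
    frame_interval
        Time between consecutive frames, in seconds.
    pixel_size
        Lateral pixel size in micrometres (optional metadata).
    """

    data: np.ndarray
    frame_interval: float = 2.0
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be T x Y x X, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Volume:
    """A 3D fluorescence volume with physical voxel spacing.

    ``voxel_spacing`` is ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be Z x Y x X, got shape {self.data.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive numbers")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.voxel_spacing)) == 1


@dataclass
class MaskStack:
    """Per-frame binary masks aligned to a :class:`Movie`.

    ``role`` records what the masks delineate: ``"cell"``, ``"ruffle"``,
    ``"protrusive"`` or ``"non_protrusive"``.
    """

    masks: np.ndarray
    role: str = "cell"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("mask stack must be T x Y x X")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks.shape


@dataclass
class SpotList:
    """Detected point sources in a volume.

    ``centers`` is an ``(n, 3)`` array of ``(z, y, x)`` voxel coordinates,
    ``scales`` the per-spot Gaussian sigma estimate (voxels) and
    ``responses`` the detector response at the detection.
    """

    centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    scales: np.ndarray = field(default_factory=lambda: np.empty((0,)))
    responses: np.ndarray = field(default_factory=lambda: np.empty((0,)))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.scales = np.asarray(self.scales, dtype=np.float64).reshape(-1)
        self.responses = np.asarray(self.responses, dtype=np.float64).reshape(-1)
        if not (len(self.centers) == len(self.scales) == len(self.responses)):
            raise ValueError("centers, scales and responses must have equal length")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class CellMask3D:
    """A binary 3D cell mask (Z x Y x X)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("cell mask must be Z x Y x X")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
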