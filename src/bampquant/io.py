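"""TIFF/CSV/YAML readers and writers plus the run manifest.

Conventions: movies are multi-page grayscale TIFFs with one page per
frame (T x Y x X), volumes one page per z-slice (Z x Y x X); integer
pixel data is promoted to float64 on read without changing values;
masks round-trip as 8-bit TIFFs; tables are CSV with a stable column
order; every run writes a JSON manifest recording the resolved
configuration, package version and seed.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import Movie, Volume

__all__ = [
    "read_movie",
    "read_volume",
    "write_movie",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_params_yaml",
    "write_manifest",
    "write_table",
    "package_version",
]


def package_version() -> str:
    try:
        return _pkg_version("bampquant")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a multi-page grayscale TIFF, got array of shape {arr.shape}; "
            "RGB or higher-dimensional stacks are not supported"
        )
    if arr.shape[0] == 0:
        raise ValueError(f"{path}: TIFF contains no pages")
    return arr.astype(np.float64)


def read_movie(
    path: str | Path, frame_interval: float = 2.0, pixel_size: Optional[float] = None
) -> Movie:
    """Read a T x Y x X movie from a multi-page grayscale TIFF.

    Integer data is promoted to float64 without value change. The frame
    interval is metadata the TIFF does not reliably carry, so it is passed
    explicitly (seconds).
    """
    return Movie(_read_stack(path), frame_interval=frame_interval, pixel_size=pixel_size)


def read_volume(
    path: str | Path, voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> Volume:
    """Read a Z x Y x X volume from a multi-page grayscale TIFF."""
    return Volume(_read_stack(path), voxel_spacing=voxel_spacing)


def _write_stack(path: str | Path, data: np.ndarray, quantize_16bit: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if quantize_16bit:
        lo, hi = float(data.min()), float(data.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        out = np.round((data - lo) * scale).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            out,
            photometric="minisblack",
            metadata={"quantization": {"offset": lo, "scale": scale}},
        )
    else:
        tifffile.imwrite(str(path), data.astype(np.float32), photometric="minisblack")


def write_movie(path: str | Path, movie: Movie, quantize_16bit: bool = False) -> None:
    """Write a movie as a multi-page TIFF (float32 by default; optionally
    min-max quantized to 16 bit, with the scaling recorded in metadata)."""
    _write_stack(path, movie.data, quantize_16bit)


def write_volume(path: str | Path, volume: Volume, quantize_16bit: bool = False) -> None:
    _write_stack(path, volume.data, quantize_16bit)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask (2D or stack) as an 8-bit TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    tifffile.imwrite(str(path), arr, photometric="minisblack", compression="zlib")


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def read_params_yaml(path: str | Path) -> dict[str, Any]:
    """Read a YAML parameter file into a plain dict (empty file → {})."""
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def write_table(path: str | Path, table: pd.DataFrame, columns: Optional[list[str]] = None) -> None:
    """Write a CSV with a stable, explicit column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        table = table[columns]
    table.to_csv(path, index=False)


def write_manifest(
    out_dir: str | Path, config: Mapping[str, Any], seed: Optional[int] = None
) -> Path:
    """Serialize the resolved configuration, package version and seed next
    to the outputs of a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "bampquant",
        "version": package_version(),
        "seed": seed,
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
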