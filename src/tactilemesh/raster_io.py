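"""Image decoding and normalized intensity grids.

Decodes PNG/JPEG/TIFF input into an 8-bit :class:`RasterImage`, converts it
to a normalized grayscale :class:`IntensityGrid` (values in [0, 1]) and
optionally resamples the grid down to a printable working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy.ndimage import map_coordinates

from .errors import DegenerateImageError, ParameterError, UnsupportedImageError

__all__ = [
    "RasterImage",
    "IntensityGrid",
    "load_image",
    "to_grayscale",
    "resample_grid",
    "DEFAULT_MAX_DIM",
]

#: Default working-resolution cap (grid nodes along the larger axis).
#: Bounds a full plate solid below ~530k triangles.
DEFAULT_MAX_DIM = 256

# Rec. 601 luma weights; they sum to exactly 1.0.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RasterImage:
    """Decoded 8-bit pixel grid, row 0 = top of the image.

    ``data`` has shape ``(height, width)`` for 1-channel images and
    ``(height, width, 3)`` for RGB.
    """

    width: int
    height: int
    channels: int
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.width < 2 or self.height < 2:
            raise DegenerateImageError(
                f"degenerate image: {self.width}x{self.height} (need at least 2x2)"
            )
        if self.channels not in (1, 3):
            raise ParameterError(f"channels must be 1 or 3, got {self.channels}")
        expected = (self.height, self.width) if self.channels == 1 else (self.height, self.width, 3)
        if self.data.shape != expected:
            raise ParameterError(
                f"data shape {self.data.shape} does not match declared {expected}"
            )
        if self.data.dtype != np.uint8:
            raise ParameterError(f"data must be uint8, got {self.data.dtype}")


@dataclass(frozen=True)
class IntensityGrid:
    """Row-major scalar field with every value in [0, 1]."""

    rows: int
    cols: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ParameterError(f"grid must be at least 2x2, got {self.rows}x{self.cols}")
        if self.values.shape != (self.rows, self.cols):
            raise ParameterError(
                f"values shape {self.values.shape} != ({self.rows}, {self.cols})"
            )
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < 0.0 or vmax > 1.0:
            raise ParameterError(f"intensity values outside [0, 1]: min={vmin}, max={vmax}")


def load_image(path) -> RasterImage:
    """Decode ``path`` into a :class:`RasterImage`.

    16-bit grayscale inputs are rescaled to 8-bit by integer division by 257;
    an alpha channel is composited over white and then dropped.
    """
    p = Path(path)
    if not p.exists():
        raise UnsupportedImageError(f"unsupported image: {p} (file does not exist)")
    try:
        with Image.open(p) as im:
            im.load()
            return _from_pil(im)
    except (DegenerateImageError, ParameterError):
        raise
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError) as exc:
        raise UnsupportedImageError(f"unsupported image: {p} ({exc})") from exc


def _from_pil(im: Image.Image) -> RasterImage:
    if im.width == 0 or im.height == 0:
        raise DegenerateImageError(f"degenerate image: {im.width}x{im.height}")

    mode = im.mode
    if mode.startswith("I"):  # 16-bit (or 32-bit int) grayscale
        arr = np.asarray(im, dtype=np.int64)
        arr = np.clip(arr, 0, 65535) // 257
        return RasterImage(im.width, im.height, 1, arr.astype(np.uint8))

    if mode == "P":
        mode = "RGBA" if "transparency" in im.info else "RGB"
        im = im.convert(mode)
    if mode in ("RGBA", "LA", "PA"):
        bg = Image.new("RGBA", im.size, (255, 255, 255, 255))
        im = Image.alpha_composite(bg, im.convert("RGBA")).convert("RGB")
        mode = "RGB"
    if mode not in ("L", "1", "RGB"):
        im = im.convert("RGB")
        mode = "RGB"
    if mode == "1":
        im = im.convert("L")
        mode = "L"

    arr = np.asarray(im, dtype=np.uint8)
    channels = 1 if mode == "L" else 3
    return RasterImage(im.width, im.height, channels, arr)


def to_grayscale(img: RasterImage) -> IntensityGrid:
    """Map an image to normalized intensity.

    1-channel data passes through as ``value / 255``; RGB uses the Rec. 601
    luma ``Y = 0.299 R + 0.587 G + 0.114 B`` before normalization.
    """
    if img.channels == 1:
        values = img.data.astype(np.float64) / 255.0
    else:
        values = img.data.astype(np.float64) @ _LUMA / 255.0
    values = np.clip(values, 0.0, 1.0)
    return IntensityGrid(img.height, img.width, values)


def resample_grid(grid: IntensityGrid, max_dim: int = DEFAULT_MAX_DIM) -> IntensityGrid:
    """Bilinearly downsample so the larger dimension equals ``max_dim``.

    Returns the input unchanged when it already fits. Sample positions are
    corner-aligned so corner values are preserved exactly.
    """
    if max_dim < 2:
        raise ParameterError(f"max_dim must be >= 2, got {max_dim}")
    rows, cols = grid.rows, grid.cols
    larger = max(rows, cols)
    if larger <= max_dim:
        return grid
    scale = max_dim / larger
    new_rows = max_dim if rows == larger else max(2, round(rows * scale))
    new_cols = max_dim if cols == larger else max(2, round(cols * scale))

    rr = np.linspace(0.0, rows - 1, new_rows)
    cc = np.linspace(0.0, cols - 1, new_cols)
    coords = np.meshgrid(rr, cc, indexing="ij")
    out = map_coordinates(grid.values, coords, order=1, mode="nearest")
    out = np.clip(out, 0.0, 1.0)
    return IntensityGrid(new_rows, new_cols, out)
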