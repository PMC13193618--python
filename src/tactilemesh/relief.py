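"""Intensity grid -> physical heightmap (mm).

The relief stage applies the optional inversion, optional Gaussian
smoothing and the linear intensity-to-height scaling over a solid base
slab, then supports region masking (circular plate) and height overrides
(rim annulus, slide frame).

Height convention: node (row 0, col 0) is the top-left of the source
image and maps to the *largest* y coordinate, so the printed model viewed
from above matches the photograph's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import MaskError, ParameterError
from .raster_io import IntensityGrid

__all__ = [
    "ReliefParams",
    "HeightMap",
    "build_heightmap",
    "apply_circular_mask",
    "override_annulus",
    "override_frame",
]


@dataclass(frozen=True)
class ReliefParams:
    """User-facing relief controls.

    relief_height_mm is the height of a maximum-intensity feature above the
    top of the base slab; intensity is mapped linearly, without per-image
    normalization, so identical images always produce identical heights.
    """

    relief_height_mm: float = 3.0
    base_thickness_mm: float = 2.0
    invert: bool = False
    smooth_sigma: float = 0.0

    def __post_init__(self):
        if self.relief_height_mm < 0:
            raise ParameterError(
                f"relief_height_mm must be >= 0, got {self.relief_height_mm}"
            )
        if self.base_thickness_mm <= 0:
            raise ParameterError(
                f"base_thickness_mm must be > 0, got {self.base_thickness_mm}"
            )
        if self.smooth_sigma < 0:
            raise ParameterError(f"smooth_sigma must be >= 0, got {self.smooth_sigma}")


@dataclass(frozen=True)
class HeightMap:
    """Per-node total height in mm over a rectangular node lattice.

    ``z`` has shape ``(rows, cols)``; ``mask`` marks included nodes.
    Node (r, c) sits at physical position ``x = c * dx``,
    ``y = (rows - 1 - r) * dy``.
    """

    rows: int
    cols: int
    dx: float
    dy: float
    z: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise ParameterError(f"node spacing must be positive, got ({self.dx}, {self.dy})")
        if self.z.shape != (self.rows, self.cols):
            raise ParameterError(f"z shape {self.z.shape} != ({self.rows}, {self.cols})")
        if self.mask.shape != self.z.shape or self.mask.dtype != bool:
            raise ParameterError("mask must be a boolean array matching z")

    @property
    def x_coords(self) -> np.ndarray:
        return np.arange(self.cols) * self.dx

    @property
    def y_coords(self) -> np.ndarray:
        return (self.rows - 1 - np.arange(self.rows)) * self.dy

    @property
    def width_mm(self) -> float:
        return (self.cols - 1) * self.dx

    @property
    def height_mm(self) -> float:
        return (self.rows - 1) * self.dy

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (rows, cols) with per-node positions."""
        return np.meshgrid(self.x_coords, self.y_coords, indexing="xy")


def build_heightmap(
    grid: IntensityGrid,
    params: ReliefParams,
    physical_width_mm: float,
    physical_height_mm: float | None = None,
) -> HeightMap:
    """Scale intensity linearly into height over the base slab.

    ``z = base + relief * e`` where ``e = 1 - I`` when inverted, else ``I``;
    smoothing (reflect boundary) is applied to ``e`` before scaling.
    Node spacing is square (``dy = dx``) unless ``physical_height_mm``
    forces a different vertical pitch.
    """
    if physical_width_mm <= 0:
        raise ParameterError(f"physical_width_mm must be > 0, got {physical_width_mm}")
    e = (1.0 - grid.values) if params.invert else grid.values.copy()
    if params.smooth_sigma > 0:
        e = gaussian_filter(e, sigma=params.smooth_sigma, mode="reflect")
        e = np.clip(e, 0.0, 1.0)
    z = params.base_thickness_mm + params.relief_height_mm * e
    dx = physical_width_mm / (grid.cols - 1)
    if physical_height_mm is None:
        dy = dx
    else:
        if physical_height_mm <= 0:
            raise ParameterError(
                f"physical_height_mm must be > 0, got {physical_height_mm}"
            )
        dy = physical_height_mm / (grid.rows - 1)
    mask = np.ones_like(z, dtype=bool)
    return HeightMap(grid.rows, grid.cols, dx, dy, z, mask)


def _radial_distance(hm: HeightMap, center: tuple[float, float]) -> np.ndarray:
    xx, yy = hm.node_positions()
    return np.hypot(xx - center[0], yy - center[1])


def apply_circular_mask(
    hm: HeightMap, center: tuple[float, float], radius_mm: float
) -> HeightMap:
    """Restrict inclusion to nodes within ``radius_mm`` of ``center``.

    At least one fully included 2x2 node block must survive, otherwise no
    printable cell remains and a :class:`MaskError` is raised.
    """
    if radius_mm <= 0:
        raise ParameterError(f"radius_mm must be > 0, got {radius_mm}")
    dist = _radial_distance(hm, center)
    mask = hm.mask & (dist <= radius_mm + 1e-9)
    blocks = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]
    if not blocks.any():
        raise MaskError("mask removed all content (no 2x2 node block remains)")
    return replace(hm, mask=mask)


def override_annulus(
    hm: HeightMap,
    center: tuple[float, float],
    r_inner_mm: float,
    r_outer_mm: float,
    z_mm: float,
) -> HeightMap:
    """Set z exactly to ``z_mm`` on included nodes with radial distance in
    [r_inner_mm, r_outer_mm]; used to render a feelable plate rim."""
    if not (0 <= r_inner_mm < r_outer_mm):
        raise ParameterError(
            f"need 0 <= r_inner < r_outer, got ({r_inner_mm}, {r_outer_mm})"
        )
    if z_mm <= 0:
        raise ParameterError(f"z_mm must be > 0, got {z_mm}")
    dist = _radial_distance(hm, center)
    sel = hm.mask & (dist >= r_inner_mm - 1e-9) & (dist <= r_outer_mm + 1e-9)
    z = hm.z.copy()
    z[sel] = z_mm
    return replace(hm, z=z)


def override_frame(hm: HeightMap, frame_width_mm: float, z_mm: float) -> HeightMap:
    """Set z to ``z_mm`` on the rectangular border band of width
    ``frame_width_mm``; used to render a feelable slide frame."""
    if frame_width_mm <= 0:
        raise ParameterError(f"frame_width_mm must be > 0, got {frame_width_mm}")
    if z_mm <= 0:
        raise ParameterError(f"z_mm must be > 0, got {z_mm}")
    xx, yy = hm.node_positions()
    eps = 1e-9
    band = (
        (xx <= frame_width_mm + eps)
        | (xx >= hm.width_mm - frame_width_mm - eps)
        | (yy <= frame_width_mm + eps)
        | (yy >= hm.height_mm - frame_width_mm - eps)
    )
    sel = hm.mask & band
    z = hm.z.copy()
    z[sel] = z_mm
    return replace(hm, z=z)
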