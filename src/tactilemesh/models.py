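"""End-to-end generators: tactile plate (disc + rim) and slide (rectangle
+ frame).

Both pipelines share the stages load -> grayscale -> resample ->
heightmap -> shape-specific mask/override -> solid -> STL and report a
one-line JSON-able summary (grid size, triangle count, bounding box,
volume).  Stage failures are wrapped in :class:`PipelineError` naming the
failing stage.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from . import braille_label as bl
from . import raster_io, relief, solid_mesh, stl_format
from .errors import ParameterError, PipelineError, PlacementError, TactileMeshError
from .relief import HeightMap, ReliefParams

__all__ = ["PlateSpec", "SlideSpec", "generate_plate", "generate_slide",
           "plate_heightmap", "slide_heightmap"]

logger = logging.getLogger("tactilemesh")

#: Vertical clearance added around a braille row when reserving its margin.
_LABEL_CLEARANCE_MM = 1.5


@dataclass(frozen=True)
class PlateSpec:
    """Physical geometry of a tactile Petri-dish model.

    Defaults: 90 mm dish (standard Petri dish) with a 2 mm rim so the
    physical boundary is feelable.
    """

    diameter_mm: float = 90.0
    rim_height_mm: float = 2.0
    rim_width_mm: float = 2.0
    relief: ReliefParams = field(default_factory=ReliefParams)
    resolution: int = raster_io.DEFAULT_MAX_DIM

    def __post_init__(self):
        if self.diameter_mm <= 2 * self.rim_width_mm:
            raise ParameterError(
                f"diameter_mm ({self.diameter_mm}) must exceed twice rim_width_mm "
                f"({self.rim_width_mm})"
            )
        if self.rim_height_mm < 0 or self.rim_width_mm <= 0:
            raise ParameterError("rim_height_mm must be >= 0 and rim_width_mm > 0")
        if self.resolution < 2:
            raise ParameterError(f"resolution must be >= 2, got {self.resolution}")


@dataclass(frozen=True)
class SlideSpec:
    """Physical geometry of a tactile microscope-slide model.

    Defaults: 75 x 25 mm (standard slide).  ``height_mm=None`` derives the
    height from the image aspect ratio instead.
    """

    width_mm: float = 75.0
    height_mm: float | None = 25.0
    frame_height_mm: float = 1.5
    frame_width_mm: float = 2.0
    relief: ReliefParams = field(default_factory=ReliefParams)
    resolution: int = raster_io.DEFAULT_MAX_DIM

    def __post_init__(self):
        if self.width_mm <= 2 * self.frame_width_mm:
            raise ParameterError(
                f"width_mm ({self.width_mm}) must exceed twice frame_width_mm "
                f"({self.frame_width_mm})"
            )
        if self.height_mm is not None and self.height_mm <= 2 * self.frame_width_mm:
            raise ParameterError(
                f"height_mm ({self.height_mm}) must exceed twice frame_width_mm "
                f"({self.frame_width_mm})"
            )
        if self.frame_height_mm < 0 or self.frame_width_mm <= 0:
            raise ParameterError("frame_height_mm must be >= 0 and frame_width_mm > 0")
        if self.resolution < 2:
            raise ParameterError(f"resolution must be >= 2, got {self.resolution}")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except PipelineError:
        raise
    except TactileMeshError as exc:
        raise PipelineError(name, exc) from exc
    logger.info("stage %-12s %.3f s", name, time.perf_counter() - t0)


def plate_heightmap(grid: raster_io.IntensityGrid, spec: PlateSpec) -> HeightMap:
    """Heightmap of the plate interior: relief scaled over the base slab,
    circular mask applied, no rim yet (useful for counting oracles)."""
    hm = relief.build_heightmap(grid, spec.relief, physical_width_mm=spec.diameter_mm)
    center = (hm.width_mm / 2.0, hm.height_mm / 2.0)
    return relief.apply_circular_mask(hm, center, spec.diameter_mm / 2.0)


def slide_heightmap(grid: raster_io.IntensityGrid, spec: SlideSpec) -> HeightMap:
    return relief.build_heightmap(
        grid, spec.relief, physical_width_mm=spec.width_mm,
        physical_height_mm=spec.height_mm,
    )


def _reserve_and_emboss(
    hm: HeightMap,
    label: bl.BrailleLabel,
    base_mm: float,
    position: str,
    inset_mm: float,
    keep_out: tuple[tuple[float, float], float] | None = None,
    keep_in_rect: tuple[float, float, float, float] | None = None,  # x0, x1, y0, y1
) -> HeightMap:
    """Flatten a horizontal band to the base height and emboss the label,
    centered horizontally."""
    if position not in ("top", "bottom"):
        raise ParameterError(f"label position must be 'top' or 'bottom', got {position!r}")
    lw, lh = bl.label_extent(label)
    band_h = lh + 2 * _LABEL_CLEARANCE_MM
    if position == "bottom":
        band_lo = inset_mm
        band_hi = band_lo + band_h
    else:
        band_hi = hm.height_mm - inset_mm
        band_lo = band_hi - band_h
    if band_lo < 0 or band_hi > hm.height_mm:
        raise PlacementError("label band does not fit the model")

    xx, yy = hm.node_positions()
    sel = hm.mask & (yy >= band_lo - 1e-9) & (yy <= band_hi + 1e-9)
    z = hm.z.copy()
    z[sel] = base_mm
    flat = HeightMap(hm.rows, hm.cols, hm.dx, hm.dy, z, hm.mask)

    x0 = (hm.width_mm - lw) / 2.0
    y_top = (band_lo + band_hi) / 2.0 + label.dot_pitch_mm
    dots = [(x0 + dx_, y_top + dy_) for dx_, dy_ in bl.text_to_dots(label)]
    if keep_out is not None:
        (cx, cy), r_free = keep_out
        for x, y in dots:
            if np.hypot(x - cx, y - cy) > r_free:
                raise PlacementError(
                    f"braille dot at ({x:.1f}, {y:.1f}) would collide with the rim; "
                    "shorten the label or enlarge the plate"
                )
    if keep_in_rect is not None:
        x_lo, x_hi, y_lo, y_hi = keep_in_rect
        for x, y in dots:
            if not (x_lo <= x <= x_hi and y_lo <= y <= y_hi):
                raise PlacementError(
                    f"braille dot at ({x:.1f}, {y:.1f}) would collide with the frame; "
                    "shorten the label or enlarge the slide"
                )
    return bl.emboss_dots(flat, dots, label)


def _summarize(hm: HeightMap, mesh, out_path, volume: float) -> dict:
    lo, hi = mesh.bounding_box()
    return {
        "grid": [hm.rows, hm.cols],
        "triangles": int(mesh.n_triangles),
        "vertices": int(mesh.n_vertices),
        "bbox_mm": [[round(float(v), 6) for v in lo], [round(float(v), 6) for v in hi]],
        "volume_mm3": round(float(volume), 6),
        "out": str(out_path),
    }


def generate_plate(
    image_path,
    spec: PlateSpec,
    out_path,
    dialect: str = "binary",
    label: bl.BrailleLabel | None = None,
    label_position: str = "bottom",
) -> dict:
    """Image of an agar plate -> watertight disc-with-rim STL + summary."""
    with _stage("load"):
        img = raster_io.load_image(image_path)
    with _stage("grayscale"):
        grid = raster_io.to_grayscale(img)
    with _stage("resample"):
        grid = raster_io.resample_grid(grid, spec.resolution)
    with _stage("heightmap"):
        hm = plate_heightmap(grid, spec)
    base = spec.relief.base_thickness_mm
    center = (hm.width_mm / 2.0, hm.height_mm / 2.0)
    radius = spec.diameter_mm / 2.0
    if label is not None:
        with _stage("label"):
            hm = _reserve_and_emboss(
                hm, label, base, label_position,
                inset_mm=center[1] - radius + spec.rim_width_mm + _LABEL_CLEARANCE_MM,
                keep_out=(center, radius - spec.rim_width_mm - label.dot_diameter_mm),
            )
    with _stage("rim"):
        hm = relief.override_annulus(
            hm, center, radius - spec.rim_width_mm, radius,
            base + spec.rim_height_mm,
        )
    with _stage("solid"):
        mesh = solid_mesh.heightmap_to_solid(hm)
        volume = solid_mesh.mesh_volume(mesh)
    with _stage("write"):
        stl_format.write_stl(mesh, out_path, dialect=dialect, name="plate")
    summary = _summarize(hm, mesh, out_path, volume)
    logger.info("plate summary: %s", summary)
    return summary


def generate_slide(
    image_path,
    spec: SlideSpec,
    out_path,
    dialect: str = "binary",
    label: bl.BrailleLabel | None = None,
    label_position: str = "bottom",
) -> dict:
    """Micrograph -> watertight rectangle-with-frame STL + summary."""
    with _stage("load"):
        img = raster_io.load_image(image_path)
    with _stage("grayscale"):
        grid = raster_io.to_grayscale(img)
    with _stage("resample"):
        grid = raster_io.resample_grid(grid, spec.resolution)
    with _stage("heightmap"):
        hm = slide_heightmap(grid, spec)
    base = spec.relief.base_thickness_mm
    if label is not None:
        with _stage("label"):
            margin = spec.frame_width_mm + label.dot_diameter_mm
            hm = _reserve_and_emboss(
                hm, label, base, label_position,
                inset_mm=spec.frame_width_mm + _LABEL_CLEARANCE_MM,
                keep_in_rect=(margin, hm.width_mm - margin,
                              margin, hm.height_mm - margin),
            )
    with _stage("frame"):
        hm = relief.override_frame(
            hm, spec.frame_width_mm, base + spec.frame_height_mm
        )
    with _stage("solid"):
        mesh = solid_mesh.heightmap_to_solid(hm)
        volume = solid_mesh.mesh_volume(mesh)
    with _stage("write"):
        stl_format.write_stl(mesh, out_path, dialect=dialect, name="slide")
    summary = _summarize(hm, mesh, out_path, volume)
    logger.info("slide summary: %s", summary)
    return summary
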