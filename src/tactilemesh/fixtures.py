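"""Synthetic plate photographs and micrographs with known object counts.

Colonies/cells are rendered as Gaussian bumps on a darker background:

    I(x, y) = clip(bg + sum_k A_k * exp(-((x-x_k)^2 + (y-y_k)^2) / (2 s^2)), 0, 1)

quantized to 8 bits.  Soft edges make threshold-based counting exercise
the relief pipeline rather than the generator.  All layouts are fully
deterministic given the mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import PackingError, ParameterError
from .raster_io import RasterImage

__all__ = [
    "ColonyFieldSpec",
    "make_colony_image",
    "make_streak_image",
    "write_png",
]

_MAX_ATTEMPTS = 10_000

LAYOUTS = ("random", "ring", "streak")


@dataclass(frozen=True)
class ColonyFieldSpec:
    """Parameters of a synthetic colony/cell field."""

    seed: int
    width_px: int = 256
    height_px: int = 256
    n_objects: int = 5
    amplitude: float = 0.9
    sigma_px: float = 4.0
    min_separation_px: float = 32.0
    background: float = 0.1
    layout: str = "random"
    margin_px: float | None = None  # default: 3 sigma + 2

    def __post_init__(self):
        if self.width_px < 2 or self.height_px < 2:
            raise ParameterError("image must be at least 2x2 pixels")
        if self.n_objects < 0:
            raise ParameterError(f"n_objects must be >= 0, got {self.n_objects}")
        if not (0 < self.amplitude <= 1):
            raise ParameterError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if self.sigma_px <= 0:
            raise ParameterError(f"sigma_px must be > 0, got {self.sigma_px}")
        if self.min_separation_px < 0:
            raise ParameterError("min_separation_px must be >= 0")
        if not (0 <= self.background < 1):
            raise ParameterError(f"background must be in [0, 1), got {self.background}")
        if self.layout not in LAYOUTS:
            raise ParameterError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")

    @property
    def effective_margin_px(self) -> float:
        if self.margin_px is not None:
            return self.margin_px
        return 3.0 * self.sigma_px + 2.0


def _render(spec: ColonyFieldSpec, centers: np.ndarray, sigma: float | None = None,
            amplitude: float | None = None) -> RasterImage:
    a = spec.amplitude if amplitude is None else amplitude
    s = spec.sigma_px if sigma is None else sigma
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px].astype(np.float64)
    field = np.full((spec.height_px, spec.width_px), spec.background, dtype=np.float64)
    for cx, cy in centers:
        field += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s**2))
    field = np.clip(field, 0.0, 1.0)
    data = np.floor(field * 255.0 + 0.5).astype(np.uint8)
    return RasterImage(spec.width_px, spec.height_px, 1, data)


def _sample_in_disc(rng, spec: ColonyFieldSpec) -> np.ndarray:
    """Rejection-sample n centers in the central disc, pairwise separated."""
    cx0, cy0 = (spec.width_px - 1) / 2.0, (spec.height_px - 1) / 2.0
    r_max = min(spec.width_px, spec.height_px) / 2.0 - spec.effective_margin_px
    if r_max <= 0:
        raise PackingError("image too small for the requested margin")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_objects:
        if attempts >= _MAX_ATTEMPTS:
            raise PackingError(
                f"could not place {spec.n_objects} objects with separation "
                f"{spec.min_separation_px}px in {attempts} attempts; try fewer objects"
            )
        attempts += 1
        r = r_max * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2 * math.pi)
        x, y = cx0 + r * math.cos(theta), cy0 + r * math.sin(theta)
        if all(
            math.hypot(x - px, y - py) >= spec.min_separation_px for px, py in centers
        ):
            centers.append((x, y))
    return np.asarray(centers, dtype=np.float64).reshape(-1, 2)


def _ring_centers(rng, spec: ColonyFieldSpec) -> np.ndarray:
    cx0, cy0 = (spec.width_px - 1) / 2.0, (spec.height_px - 1) / 2.0
    r_max = min(spec.width_px, spec.height_px) / 2.0 - spec.effective_margin_px
    if r_max <= 0:
        raise PackingError("image too small for the requested margin")
    radius = 0.7 * r_max
    n = spec.n_objects
    if n == 0:
        return np.empty((0, 2))
    if n * spec.min_separation_px > 2 * math.pi * radius:
        raise PackingError(
            f"ring circumference cannot hold {n} objects at separation "
            f"{spec.min_separation_px}px; try fewer objects"
        )
    jitter = rng.uniform(-0.1, 0.1, size=n) * (2 * math.pi / max(n, 1))
    angles = 2 * math.pi * np.arange(n) / n + jitter + rng.uniform(0, 2 * math.pi)
    return np.column_stack(
        [cx0 + radius * np.cos(angles), cy0 + radius * np.sin(angles)]
    )


def make_colony_image(spec: ColonyFieldSpec) -> RasterImage:
    """Render a plate-photograph-like image with a known object count."""
    rng = np.random.default_rng(spec.seed)
    if spec.layout == "streak":
        return make_streak_image(spec)
    if spec.n_objects == 0:
        centers = np.empty((0, 2))
    elif spec.layout == "ring":
        centers = _ring_centers(rng, spec)
    else:
        centers = _sample_in_disc(rng, spec)
    return _render(spec, centers)


def make_streak_image(
    spec: ColonyFieldSpec, mode: str = "successful", return_segments: bool = False
):
    """Render a streak-plate pattern.

    ``successful``: 4 zigzag segments with strictly decreasing colony
    density, ending in isolated colonies.  ``overgrown``: a dense
    confluent field forming one large connected smear.  With
    ``return_segments`` the per-segment center arrays are returned too.
    """
    if mode not in ("successful", "overgrown"):
        raise ParameterError(f"streak mode must be 'successful' or 'overgrown', got {mode!r}")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    r_plate = min(w, h) / 2.0 - spec.effective_margin_px
    if r_plate <= 0:
        raise PackingError("image too small for the requested margin")

    if mode == "overgrown":
        # Dense jittered lattice of overlapping bumps covering the dish.
        step = 1.6 * spec.sigma_px
        pts = []
        for gy in np.arange(cy0 - r_plate, cy0 + r_plate + step, step):
            for gx in np.arange(cx0 - r_plate, cx0 + r_plate + step, step):
                jx, jy = rng.uniform(-0.2 * step, 0.2 * step, size=2)
                x, y = gx + jx, gy + jy
                if math.hypot(x - cx0, y - cy0) <= 0.92 * r_plate:
                    pts.append((x, y))
        centers = np.asarray(pts).reshape(-1, 2)
        img = _render(spec, centers)
        return (img, [centers]) if return_segments else img

    # Successful streak: zigzag path through 4 segments, decreasing counts.
    base = max(6, spec.n_objects)
    counts = [4 * base, 2 * base, base, max(2, base // 2)]
    waypoints = np.array(
        [
            (cx0 - 0.8 * r_plate, cy0 - 0.8 * r_plate),
            (cx0 + 0.8 * r_plate, cy0 - 0.5 * r_plate),
            (cx0 - 0.8 * r_plate, cy0 + 0.0 * r_plate),
            (cx0 + 0.8 * r_plate, cy0 + 0.5 * r_plate),
            (cx0 - 0.6 * r_plate, cy0 + 0.8 * r_plate),
        ]
    )
    segments = []
    for seg, n in enumerate(counts):
        p0, p1 = waypoints[seg], waypoints[seg + 1]
        t = rng.uniform(0.0, 1.0, size=n)
        jitter = rng.normal(scale=1.2 * spec.sigma_px, size=(n, 2))
        seg_pts = p0 + t[:, None] * (p1 - p0) + jitter
        # Keep everything inside the dish.
        d = np.hypot(seg_pts[:, 0] - cx0, seg_pts[:, 1] - cy0)
        segments.append(seg_pts[d <= 0.95 * r_plate])
    img = _render(spec, np.concatenate(segments))
    return (img, segments) if return_segments else img


def write_png(img: RasterImage, path) -> Path:
    """Write a RasterImage to PNG losslessly."""
    p = Path(path)
    mode = "L" if img.channels == 1 else "RGB"
    Image.fromarray(img.data, mode=mode).save(p, format="PNG")
    return p
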