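"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the library's own code paths: the volume
oracle is a prism decomposition computed straight from the heightmap, the
triangle-count oracle enumerates cells and boundary edges, and braille
patterns are checked against the Unicode braille block.
"""

from __future__ import annotations

import numpy as np
import pytest
from PIL import Image

from tactilemesh.relief import HeightMap


# ---------------------------------------------------------------------------
# heightmap builders


def make_heightmap(z, dx=1.0, dy=None, mask=None) -> HeightMap:
    z = np.asarray(z, dtype=np.float64)
    rows, cols = z.shape
    if mask is None:
        mask = np.ones_like(z, dtype=bool)
    return HeightMap(rows, cols, dx, dx if dy is None else dy, z, np.asarray(mask, bool))


def random_heightmap(rng, rows, cols, dx=1.0, mask=None) -> HeightMap:
    """Random relief (base 1..3 mm plus up to 3 mm of texture)."""
    z = 1.0 + 2.0 * rng.random() + 3.0 * rng.random((rows, cols))
    return make_heightmap(z, dx=dx, mask=mask)


def disc_mask(rows, cols, center_rc, radius_nodes) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_nodes**2


def rect_mask(rows, cols, r0, r1, c0, c1) -> np.ndarray:
    m = np.zeros((rows, cols), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def has_cell(mask: np.ndarray) -> bool:
    return bool((mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]).any())


def random_simply_connected_mask(rng, rows, cols) -> np.ndarray:
    """Random convex-ish masks (full grid, disc, or rectangle window).

    Convex node sets guarantee a single genus-0 cell region, so the Euler
    characteristic of the resulting solid is exactly 2.
    """
    while True:
        kind = rng.integers(0, 3)
        if kind == 0:
            m = np.ones((rows, cols), dtype=bool)
        elif kind == 1:
            center = (rng.uniform(0, rows - 1), rng.uniform(0, cols - 1))
            radius = rng.uniform(1.5, max(rows, cols))
            m = disc_mask(rows, cols, center, radius)
        else:
            r0 = rng.integers(0, rows - 1)
            r1 = rng.integers(r0 + 2, rows + 1)
            c0 = rng.integers(0, cols - 1)
            c1 = rng.integers(c0 + 2, cols + 1)
            m = rect_mask(rows, cols, r0, r1, c0, c1)
        if has_cell(m):
            return m


# ---------------------------------------------------------------------------
# independent oracles


def prism_volume_oracle(hm: HeightMap) -> float:
    """Volume by prism decomposition: per emitted cell, two triangles along
    the fixed (low-row, low-col) -> (high-row, high-col) diagonal, each
    contributing area x mean corner height."""
    z, mask = hm.z, hm.mask
    cells = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]
    area = hm.dx * hm.dy / 2.0
    total = 0.0
    for r, c in zip(*np.nonzero(cells)):
        za, zb, zc, zd = z[r, c], z[r, c + 1], z[r + 1, c + 1], z[r + 1, c]
        total += area * (za + zd + zc) / 3.0  # triangle A-D-C
        total += area * (za + zc + zb) / 3.0  # triangle A-C-B
    return total


def triangle_count_oracle(mask: np.ndarray) -> int:
    """Enumerate cells and exposed cell edges (no closed-form formula)."""
    cells = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]
    n_cells = int(cells.sum())
    rows, cols = cells.shape
    exposed = 0
    for r in range(rows):
        for c in range(cols):
            if not cells[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or not cells[nr, nc]:
                    exposed += 1
    return 4 * n_cells + 2 * exposed


#: Unicode braille block, letters a-z (independent of the package table).
UNICODE_BRAILLE_LETTERS = {
    "A": 0x2801, "B": 0x2803, "C": 0x2809, "D": 0x2819, "E": 0x2811,
    "F": 0x280B, "G": 0x281B, "H": 0x2813, "I": 0x280A, "J": 0x281A,
    "K": 0x2805, "L": 0x2807, "M": 0x280D, "N": 0x281D, "O": 0x2815,
    "P": 0x280F, "Q": 0x281F, "R": 0x2817, "S": 0x280E, "T": 0x281E,
    "U": 0x2825, "V": 0x2827, "W": 0x283A, "X": 0x282D, "Y": 0x283D,
    "Z": 0x2835,
}


def unicode_dot_set(codepoint: int) -> set[int]:
    bits = codepoint - 0x2800
    return {i + 1 for i in range(6) if (bits >> i) & 1}


# ---------------------------------------------------------------------------
# image files


@pytest.fixture
def tmp_png(tmp_path):
    """Factory writing an arbitrary uint8/uint16 array as a PNG."""

    def _write(arr, name="img.png"):
        p = tmp_path / name
        Image.fromarray(np.asarray(arr)).save(p)
        return p

    return _write


@pytest.fixture
def white_png(tmp_png):
    return tmp_png(np.full((2, 2), 255, dtype=np.uint8), "white.png")


@pytest.fixture
def gradient_png(tmp_png):
    """64x64 horizontal ramp, handy for relief tests."""
    row = np.linspace(0, 255, 64).astype(np.uint8)
    return tmp_png(np.tile(row, (64, 1)), "gradient.png")
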