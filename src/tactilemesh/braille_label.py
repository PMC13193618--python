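"""Grade-1 (uncontracted) braille embossing on a flat heightmap margin.

Dots are numbered 1-2-3 down the left column and 4-5-6 down the right
column of the 2x3 cell.  Digits reuse the letter patterns A-J and each run
of digits is prefixed with the number sign (dots 3-4-5-6).  Dimensional
defaults follow common tactile-signage practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, PlacementError
from .relief import HeightMap

__all__ = ["BrailleLabel", "text_to_dots", "emboss_dots", "label_extent"]

# Standard Grade-1 braille patterns, letters A-Z.
LETTER_DOTS: dict[str, tuple[int, ...]] = {
    "A": (1,),
    "B": (1, 2),
    "C": (1, 4),
    "D": (1, 4, 5),
    "E": (1, 5),
    "F": (1, 2, 4),
    "G": (1, 2, 4, 5),
    "H": (1, 2, 5),
    "I": (2, 4),
    "J": (2, 4, 5),
    "K": (1, 3),
    "L": (1, 2, 3),
    "M": (1, 3, 4),
    "N": (1, 3, 4, 5),
    "O": (1, 3, 5),
    "P": (1, 2, 3, 4),
    "Q": (1, 2, 3, 4, 5),
    "R": (1, 2, 3, 5),
    "S": (2, 3, 4),
    "T": (2, 3, 4, 5),
    "U": (1, 3, 6),
    "V": (1, 2, 3, 6),
    "W": (2, 4, 5, 6),
    "X": (1, 3, 4, 6),
    "Y": (1, 3, 4, 5, 6),
    "Z": (1, 3, 5, 6),
}

NUMBER_SIGN = (3, 4, 5, 6)

# Digits 1..9, 0 map to letters A..J after a number sign.
DIGIT_TO_LETTER = {str(d): "ABCDEFGHIJ"[d - 1] for d in range(1, 10)} | {"0": "J"}

MAX_CELLS = 20


@dataclass(frozen=True)
class BrailleLabel:
    """Label text plus physical dot geometry (all sizes in mm)."""

    text: str
    dot_height_mm: float = 0.6
    dot_diameter_mm: float = 1.5
    dot_pitch_mm: float = 2.5
    cell_pitch_mm: float = 6.0

    def __post_init__(self):
        if not self.text:
            raise ParameterError("label text must be non-empty")
        for dim in ("dot_height_mm", "dot_diameter_mm", "dot_pitch_mm", "cell_pitch_mm"):
            if getattr(self, dim) <= 0:
                raise ParameterError(f"{dim} must be > 0")
        bad = sorted({ch for ch in self.text.upper() if ch not in LETTER_DOTS and not ch.isdigit() and ch != " "})
        if bad:
            raise ParameterError(f"unsupported label character(s): {', '.join(map(repr, bad))}")
        if len(expand_cells(self.text)) > MAX_CELLS:
            raise ParameterError(
                f"label exceeds {MAX_CELLS} braille cells after digit-prefix expansion"
            )


def expand_cells(text: str) -> list[tuple[int, ...]]:
    """Per-cell dot patterns, inserting a number sign before each digit run."""
    cells: list[tuple[int, ...]] = []
    in_digits = False
    for ch in text.upper():
        if ch == " ":
            cells.append(())
            in_digits = False
        elif ch.isdigit():
            if not in_digits:
                cells.append(NUMBER_SIGN)
                in_digits = True
            cells.append(LETTER_DOTS[DIGIT_TO_LETTER[ch]])
        else:
            cells.append(LETTER_DOTS[ch])
            in_digits = False
    return cells


def text_to_dots(label: BrailleLabel) -> list[tuple[float, float]]:
    """Dot centers in mm, label-local coordinates.

    The first cell's dot-1 sits at (0, 0); x grows rightward across cells,
    y decreases downward through dot rows (y up, matching heightmaps).
    """
    dots: list[tuple[float, float]] = []
    for k, cell in enumerate(expand_cells(label.text)):
        x0 = k * label.cell_pitch_mm
        for d in cell:
            col = 0 if d <= 3 else 1
            row = (d - 1) % 3
            dots.append((x0 + col * label.dot_pitch_mm, -row * label.dot_pitch_mm))
    return dots


def label_extent(label: BrailleLabel) -> tuple[float, float]:
    """(width, height) in mm of the dot bounding box for the label."""
    n_cells = len(expand_cells(label.text))
    width = (n_cells - 1) * label.cell_pitch_mm + label.dot_pitch_mm
    return width, 2 * label.dot_pitch_mm


def emboss_dots(
    hm: HeightMap,
    dots: list[tuple[float, float]],
    label: BrailleLabel,
) -> HeightMap:
    """Raise spherical-cap dots at absolute (x, y) positions on ``hm``.

    Every node within dot_diameter/2 of a dot center gains the cap profile
    (clamped to dot_height); all other nodes are bitwise unchanged.  Each
    dot must land on included nodes of a locally flat margin.
    """
    if not dots:
        return hm
    radius = label.dot_diameter_mm / 2.0
    if label.dot_diameter_mm < 2 * max(hm.dx, hm.dy):
        raise ParameterError(
            "grid resolution too coarse for braille: fewer than 3 nodes span a "
            f"dot diameter ({label.dot_diameter_mm} mm vs spacing "
            f"{max(hm.dx, hm.dy):.3g} mm)"
        )
    # Sphere of base radius R and cap height h.
    h = label.dot_height_mm
    s = (radius**2 + h**2) / (2 * h)

    xx, yy = hm.node_positions()
    z = hm.z.copy()
    for x0, y0 in dots:
        dist = np.hypot(xx - x0, yy - y0)
        sel = dist <= radius + 1e-9
        if not sel.any():
            raise PlacementError(f"braille dot at ({x0:.2f}, {y0:.2f}) covers no grid node")
        if not hm.mask[sel].all():
            raise PlacementError(
                f"braille dot at ({x0:.2f}, {y0:.2f}) falls outside the included region"
            )
        flat = hm.z[sel]
        if float(flat.max() - flat.min()) > 1e-6:
            raise PlacementError(
                f"braille dot at ({x0:.2f}, {y0:.2f}) is not on a flat margin"
            )
        cap = np.sqrt(np.maximum(s**2 - dist[sel] ** 2, 0.0)) - (s - h)
        z[sel] = hm.z[sel] + np.clip(cap, 0.0, h)
    return replace(hm, z=z)
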