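"""Grids of circular regions of interest (one disk per well).

A plate is described by a :class:`GridSpec` — rows × columns of circular
ROIs with a common diameter, laid out from the centre of the top-left well
with fixed centre-to-centre pitches.  ``build_masks`` realises the grid as
pixel sets against a concrete frame size, in row-major order with
plate-style labels (A1, A2, …, B1, …).

Conventions (fixed so results are bit-exact and testable): image
coordinates are 0-based with the origin at the top-left; a centre ``(x, y)``
has ``x`` along columns and ``y`` along rows; pixel centres sit at integer
coordinates; a pixel belongs to an ROI iff its Euclidean distance to the
ROI centre is ≤ radius (boundary inclusive).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def row_label(i: int) -> str:
    """0 → 'A', 25 → 'Z', 26 → 'AA' (spreadsheet-style row letters)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return letters


@dataclass(frozen=True)
class GridSpec:
    """Geometric description of an n_rows × n_cols grid of circular ROIs."""

    n_rows: int
    n_cols: int
    origin: tuple[float, float]  # (x0, y0) centre of ROI A1, pixels
    pitch_x: float
    pitch_y: float
    diameter: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.n_cols > 1 and self.pitch_x <= 0:
            raise ValueError("pitch_x must be positive for multi-column grids")
        if self.n_rows > 1 and self.pitch_y <= 0:
            raise ValueError("pitch_y must be positive for multi-row grids")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def labels(self) -> list[str]:
        return [
            f"{row_label(r)}{c + 1}" for r in range(self.n_rows) for c in range(self.n_cols)
        ]

    def centres(self) -> list[tuple[float, float]]:
        x0, y0 = self.origin
        return [
            (x0 + c * self.pitch_x, y0 + r * self.pitch_y)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


@dataclass(frozen=True)
class ROIMask:
    """A realised circular ROI: its label, geometry and member pixels."""

    label: str
    centre: tuple[float, float]  # (x, y)
    radius: float
    pixels: np.ndarray = field(repr=False)  # (N, 2) int array of (row, col)

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def rows(self) -> np.ndarray:
        return self.pixels[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.pixels[:, 1]

    def pixel_set(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in self.pixels.tolist()}


def _disk_pixels(cx: float, cy: float, radius: float) -> np.ndarray:
    lo_r, hi_r = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
    lo_c, hi_c = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
    rr, cc = np.mgrid[lo_r : hi_r + 1, lo_c : hi_c + 1]
    inside = (cc - cx) ** 2 + (rr - cy) ** 2 <= radius**2
    return np.column_stack([rr[inside], cc[inside]])


def build_masks(grid: GridSpec, frame_height: int, frame_width: int) -> list[ROIMask]:
    """Realise a grid against a frame, in row-major order labelled A1, A2, …

    Every ROI disk must lie fully inside the frame; an offending ROI is
    reported by label.
    """
    if frame_height <= 0 or frame_width <= 0:
        raise ValueError("frame dimensions must be positive")
    masks = []
    r = grid.radius
    for label, (cx, cy) in zip(grid.labels(), grid.centres()):
        if cx - r < 0 or cy - r < 0 or cx + r > frame_width - 1 or cy + r > frame_height - 1:
            raise ValueError(
                f"ROI {label} (centre=({cx:g},{cy:g}), radius={r:g}) extends beyond "
                f"the {frame_height}x{frame_width} frame"
            )
        masks.append(ROIMask(label=label, centre=(cx, cy), radius=r, pixels=_disk_pixels(cx, cy, r)))
    return masks


def overlay_image(
    masks: Sequence[ROIMask], frame_height: int, frame_width: int
) -> np.ndarray:
    """An RGB overlay for visual verification: each ROI disk tinted green.

    Suitable for saving on top of (or next to) a video frame to confirm the
    grid lines up with the wells.
    """
    img = np.zeros((frame_height, frame_width, 3), dtype=np.uint8)
    for m in masks:
        img[m.rows, m.cols] = (0, 200, 0)
        cy, cx = int(round(m.centre[1])), int(round(m.centre[0]))
        img[cy, cx] = (255, 0, 0)
    return img


def masks_overlap(masks: Sequence[ROIMask]) -> tuple[bool, list[tuple[str, str]]]:
    """True (plus the offending label pairs) iff any two pixel sets intersect."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    offending = []
    sets = [m.pixel_set() for m in masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if sets[i] & sets[j]:
                offending.append((masks[i].label, masks[j].label))
    return bool(offending), offending
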