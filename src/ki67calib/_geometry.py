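"""Discrete disc footprints and line-crossing predicates.

A nuclear profile is represented on the pixel lattice by the set of pixels
whose centres fall inside its circle.  Both the renderer and the counting
frames use this single rasterization, so "what the observer sees" and "what
the frame counts" are the same object by construction.

Coordinate convention: 0-based pixel coordinates, x right, y down.  Pixel
``(x, y)`` is the unit square whose centre is at integer ``(x, y)``.  Frame
interiors are half-open, so the vertical grid line "at x = c" separates pixel
columns ``c - 1`` and ``c`` (and similarly for horizontal lines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscFootprint:
    """Run-length representation of a rasterized disc.

    Row ``y0 + k`` spans pixel columns ``xmin[k] .. xmax[k]`` inclusive.
    """

    y0: int
    xmin: np.ndarray
    xmax: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.xmin)

    @property
    def y_last(self) -> int:
        return self.y0 + self.n_rows - 1

    @property
    def n_pixels(self) -> int:
        return int(np.sum(self.xmax - self.xmin + 1))

    def pixel_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) of every pixel in the footprint."""
        counts = self.xmax - self.xmin + 1
        ys = np.repeat(np.arange(self.y0, self.y0 + self.n_rows), counts)
        xs = np.concatenate(
            [np.arange(lo, hi + 1) for lo, hi in zip(self.xmin, self.xmax)]
        ) if self.n_rows else np.empty(0, dtype=int)
        return xs, ys

    def bbox(self) -> tuple[int, int, int, int]:
        """(xmin, ymin, xmax, ymax), all inclusive."""
        return int(self.xmin.min()), self.y0, int(self.xmax.max()), self.y_last

    # -- predicates used by the counting rules --------------------------------

    def intersects_rect(self, left: int, top: int, right: int, bottom: int) -> bool:
        """Share at least one pixel with the half-open rect [left,right) x [top,bottom)."""
        lo = max(self.y0, top) - self.y0
        hi = min(self.y_last, bottom - 1) - self.y0
        if lo > hi:
            return False
        rows = slice(lo, hi + 1)
        return bool(np.any((self.xmin[rows] <= right - 1) & (self.xmax[rows] >= left)))

    def crosses_vline(self, c: int, y_lo: int | None = None,
                      y_hi: int | None = None) -> bool:
        """Cross the vertical grid line between pixel columns c-1 and c.

        The crossing must occur in a row within ``[y_lo, y_hi]`` (inclusive,
        ``None`` meaning unbounded): i.e. some such row holds pixels on both
        sides of the line.
        """
        lo = self.y0 if y_lo is None else max(self.y0, y_lo)
        hi = self.y_last if y_hi is None else min(self.y_last, y_hi)
        if lo > hi:
            return False
        rows = slice(lo - self.y0, hi - self.y0 + 1)
        return bool(np.any((self.xmin[rows] <= c - 1) & (self.xmax[rows] >= c)))

    def crosses_hline(self, r: int, x_lo: int | None = None,
                      x_hi: int | None = None) -> bool:
        """Cross the horizontal grid line between pixel rows r-1 and r.

        The crossing must occur at a column within ``[x_lo, x_hi]``: some such
        column holds a pixel in row r-1 and a pixel in row r.  Rows of a disc
        are intervals, so this reduces to an interval intersection.
        """
        ia, ib = r - 1 - self.y0, r - self.y0
        if ia < 0 or ib >= self.n_rows:
            return False
        lo = max(self.xmin[ia], self.xmin[ib])
        hi = min(self.xmax[ia], self.xmax[ib])
        if x_lo is not None:
            lo = max(lo, x_lo)
        if x_hi is not None:
            hi = min(hi, x_hi)
        return lo <= hi


def disc_footprint(x: float, y: float, radius: float) -> DiscFootprint:
    """Rasterize the disc of centre (x, y) and given radius (pixel units).

    A pixel belongs to the footprint iff its centre lies within ``radius`` of
    the disc centre (closed inequality).  Rows that contain no pixel are
    trimmed; a disc too small to cover any pixel centre yields an empty
    footprint.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    row_first = int(np.ceil(y - radius))
    row_last = int(np.floor(y + radius))
    rows = np.arange(row_first, row_last + 1)
    h2 = radius * radius - (rows - y) ** 2
    h = np.sqrt(np.maximum(h2, 0.0))
    xmin = np.ceil(x - h).astype(int)
    xmax = np.floor(x + h).astype(int)
    keep = (h2 >= 0) & (xmin <= xmax)
    if not np.any(keep):
        return DiscFootprint(0, np.empty(0, dtype=int), np.empty(0, dtype=int))
    idx = np.flatnonzero(keep)
    return DiscFootprint(int(rows[idx[0]]),
                         xmin[idx[0]:idx[-1] + 1],
                         xmax[idx[0]:idx[-1] + 1])
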