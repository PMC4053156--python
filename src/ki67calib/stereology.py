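"""Counting-frame stereology: the reference arm of the validation pipeline.

A square lattice of counting frames (side ``b`` px, period ``a`` px) is
overlaid on the spot.  Within each frame that touches tumour, nuclear
profiles are counted under a forbidden-line rule: profiles crossing the left
or bottom frame edges are excluded, those crossing the top or right edges are
accepted.  The percentage of positive profiles among counted tumour profiles
is the reference labelling index (the "grid count").

Because only a systematic subsample of the tissue is read, the estimate
carries a relative sampling error, summarized by the coefficient of error

    CE = t * sqrt(Cg * m / n**2)

where ``n`` is the number of frames inside the tumour, ``m`` the number of
external sides of that frame set (the boundary edge count of the union of
occupied lattice cells), ``Cg`` a grid-geometry factor (0.049 for b/a = 1/2)
and ``t`` a Student coverage factor (2 for ~95% confidence at event counts
above 30).  The CE yields a per-spot confidence interval ``li * (1 +/- CE)``.

Two forbidden-line variants are provided:

``simple``
    exactly the left and bottom frame edges, nothing more;
``gundersen``
    the classical unbiased frame, adding the upward extension of the left
    edge and the downward extension below the bottom-right corner.  Under a
    full tiling (a == b) this variant counts every convex profile exactly
    once, which is what makes exhaustive-enumeration cross-checks possible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._geometry import DiscFootprint, disc_footprint
from .errors import (AlignmentError, InvalidGridError, UndefinedLIError,
                     UndefinedSegmentsError)
from .synthetic import (CellProfile, ObserverErrorModel, SyntheticSpot,
                        TUMOUR_POSITIVE, simulate_observer_counts)

__all__ = [
    "FrameGrid", "CEParams", "GridCountResult", "AgreementReport",
    "build_grid", "frames_in_tumour", "external_segments",
    "count_frame_profiles", "coefficient_error", "confidence_interval",
    "grid_count", "ci_agreement", "COUNTING_RULES",
]

COUNTING_RULES = ("simple", "gundersen")


@dataclass(frozen=True)
class FrameGrid:
    """Systematically sampled frame lattice over an image extent.

    Lattice cell ``(i, j)`` is the frame with top-left pixel corner at
    ``(dx + i*a, dy + j*a)``; only frames fully inside the image extent are
    part of the lattice.
    """

    frame_size_px: int
    spacing_px: int
    origin_offset_px: tuple[int, int]
    lattice_cells: tuple[tuple[int, int], ...]

    def frame_origin(self, cell: tuple[int, int]) -> tuple[int, int]:
        dx, dy = self.origin_offset_px
        return dx + cell[0] * self.spacing_px, dy + cell[1] * self.spacing_px

    @property
    def n_frames(self) -> int:
        return len(self.lattice_cells)


@dataclass(frozen=True)
class CEParams:
    """Grid factor and Student coverage factor of the CE formula."""

    grid_factor_cg: float = 0.049
    student_t: float = 2.0

    def __post_init__(self):
        if self.grid_factor_cg <= 0 or self.student_t <= 0:
            raise ValueError("grid factor and Student factor must be positive")


@dataclass(frozen=True)
class GridCountResult:
    """Outcome of one grid count on one spot."""

    pos_count: int
    neg_count: int
    li_percent: float
    n_frames_in_tumour: int
    m_external_segments: int
    ce: float
    ci_low_percent: float
    ci_high_percent: float
    total_profiles: int

    def as_row(self) -> dict:
        return {
            "pos": self.pos_count, "neg": self.neg_count,
            "li": self.li_percent, "n": self.n_frames_in_tumour,
            "m": self.m_external_segments, "ce": self.ce,
            "ci_low": self.ci_low_percent, "ci_high": self.ci_high_percent,
            "total": self.total_profiles,
        }


def build_grid(image_extent_px: tuple[int, int], frame_size_px: int = 125,
               spacing_px: int = 250,
               origin_offset_px: tuple[int, int] = (0, 0)) -> FrameGrid:
    """Lay out every frame that fits fully inside ``(width, height)``."""
    w, h = image_extent_px
    b, a = int(frame_size_px), int(spacing_px)
    dx, dy = (int(v) for v in origin_offset_px)
    if b <= 0:
        raise InvalidGridError("frame size must be positive")
    if a < b:
        raise InvalidGridError(f"spacing {a} smaller than frame size {b}")
    if a > min(w, h):
        raise InvalidGridError("spacing exceeds the image extent")
    if not (0 <= dx < a and 0 <= dy < a):
        raise InvalidGridError("origin offset must lie in [0, spacing)")
    nx = (w - dx - b) // a + 1 if w - dx >= b else 0
    ny = (h - dy - b) // a + 1 if h - dy >= b else 0
    cells = tuple(itertools.product(range(nx), range(ny)))
    return FrameGrid(b, a, (dx, dy), cells)


def frames_in_tumour(grid: FrameGrid, tumour_mask: np.ndarray,
                     min_overlap_fraction: float = 0.0) -> frozenset:
    """Lattice cells whose frame overlaps the tumour mask.

    With the default ``min_overlap_fraction = 0`` any positive overlap
    qualifies (an observer marks whatever tumour shows in the frame);
    otherwise the overlap must reach that fraction of the frame area.
    """
    h, w = tumour_mask.shape
    b = grid.frame_size_px
    # summed-area table: S[y, x] = number of true pixels in [0,x) x [0,y)
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(tumour_mask, axis=0), axis=1, out=sat[1:, 1:])
    need = min_overlap_fraction * b * b
    keep = []
    for cell in grid.lattice_cells:
        x0, y0 = grid.frame_origin(cell)
        x1, y1 = min(x0 + b, w), min(y0 + b, h)
        if x0 >= w or y0 >= h:
            continue
        area = int(sat[y1, x1] - sat[y0, x1] - sat[y1, x0] + sat[y0, x0])
        if area > need or (min_overlap_fraction == 0.0 and area > 0):
            keep.append(cell)
    return frozenset(keep)


def external_segments(cells) -> int:
    """Boundary edge count of the union of occupied lattice cells.

    Equals ``4n - 2 * (# of 4-adjacent pairs)``: every cell contributes four
    sides and each adjacency hides two of them.
    """
    cells = set(cells)
    if not cells:
        raise UndefinedSegmentsError("external segments undefined for an "
                                     "empty frame set")
    adj = sum(1 for (i, j) in cells if (i + 1, j) in cells) + \
        sum(1 for (i, j) in cells if (i, j + 1) in cells)
    return 4 * len(cells) - 2 * adj


def _counted_in_frame(fp: DiscFootprint, left: int, top: int, b: int,
                      rule: str) -> bool:
    right, bottom = left + b, top + b
    if not fp.intersects_rect(left, top, right, bottom):
        return False
    if rule == "simple":
        return not (fp.crosses_vline(left, top, bottom - 1)
                    or fp.crosses_hline(bottom, left, right - 1))
    if rule == "gundersen":
        return not (fp.crosses_vline(left, None, bottom - 1)
                    or fp.crosses_hline(bottom, left, right - 1)
                    or fp.crosses_vline(right, bottom, None))
    raise ValueError(f"unknown counting rule {rule!r}")


@lru_cache(maxsize=262_144)
def _cell_footprint(cell: CellProfile) -> DiscFootprint:
    return disc_footprint(cell.x, cell.y, cell.radius_px)


class _SpotCounter:
    """Per-spot counting accelerator: footprints and bboxes built once."""

    def __init__(self, truth):
        self.cells = [c for c in truth if c.is_tumour]
        self.fps = [_cell_footprint(c) for c in self.cells]
        self.is_pos = np.array(
            [c.cell_class == TUMOUR_POSITIVE for c in self.cells], dtype=bool)
        if self.cells:
            bb = np.array([fp.bbox() for fp in self.fps])
            self.bx0, self.by0, self.bx1, self.by1 = bb.T
        else:
            self.bx0 = self.by0 = self.bx1 = self.by1 = np.empty(0, dtype=int)

    def count(self, left: int, top: int, b: int, rule: str) -> tuple[int, int]:
        cand = np.flatnonzero((self.bx1 >= left) & (self.by1 >= top)
                              & (self.bx0 < left + b) & (self.by0 < top + b))
        pos = neg = 0
        for k in cand:
            if _counted_in_frame(self.fps[k], left, top, b, rule):
                if self.is_pos[k]:
                    pos += 1
                else:
                    neg += 1
        return pos, neg


def count_frame_profiles(truth, frame, rule: str = "simple",
                         _footprints=None) -> tuple[int, int]:
    """Count (positive, negative) tumour profiles for one frame.

    ``frame`` is ``(left, top, size)`` in pixels.  A profile is counted iff
    its rasterized footprint shares a pixel with the frame and does not cross
    a forbidden line of the chosen rule; stroma and lymphocytes are never
    counted.
    """
    left, top, b = frame
    pos = neg = 0
    for k, cell in enumerate(truth):
        if not cell.is_tumour:
            continue
        fp = _footprints[k] if _footprints is not None else cell.footprint()
        # bbox prefilter: an object that cannot share a pixel with the frame
        # is never counted, whatever the rule
        x0, y0, x1, y1 = fp.bbox()
        if x1 < left or y1 < top or x0 >= left + b or y0 >= top + b:
            continue
        if _counted_in_frame(fp, left, top, b, rule):
            if cell.cell_class == TUMOUR_POSITIVE:
                pos += 1
            else:
                neg += 1
    return pos, neg


def coefficient_error(n: int, m: int, params: CEParams = CEParams()) -> float:
    """Relative sampling error ``t * sqrt(Cg * m / n^2)``."""
    if n < 1:
        raise UndefinedLIError("CE undefined for n = 0 frames", n_frames=n,
                               m_segments=m)
    if m < 0:
        raise ValueError("m must be non-negative")
    return params.student_t * float(
        np.sqrt(params.grid_factor_cg * m / (n * n)))


def confidence_interval(li_percent: float, ce: float) -> tuple[float, float]:
    """Relative CE interval ``li * (1 +/- ce)`` clamped to [0, 100]."""
    if not 0.0 <= li_percent <= 100.0:
        raise ValueError("li_percent must be in [0, 100]")
    if ce < 0:
        raise ValueError("ce must be non-negative")
    return (max(li_percent * (1.0 - ce), 0.0),
            min(li_percent * (1.0 + ce), 100.0))


def grid_count(spot: SyntheticSpot, grid: FrameGrid, rule: str = "simple",
               ce_params: CEParams = CEParams(),
               observer: ObserverErrorModel | None = None,
               min_overlap_fraction: float = 0.0) -> GridCountResult:
    """Run the full reference procedure on one spot.

    Sums forbidden-line frame counts over the frames inside the tumour,
    optionally degrades them through an observer-error model, and attaches
    the CE-based confidence interval.
    """
    cells = frames_in_tumour(grid, spot.tumour_mask, min_overlap_fraction)
    n = len(cells)
    if n == 0:
        raise UndefinedLIError("no frames inside the tumour", n_frames=0,
                               m_segments=0)
    m = external_segments(cells)
    counter = _SpotCounter(spot.truth)
    b = grid.frame_size_px
    pos = neg = 0
    for cell in sorted(cells):
        x0, y0 = grid.frame_origin(cell)
        p, q = counter.count(x0, y0, b, rule)
        pos += p
        neg += q
    if observer is not None:
        pos, neg = simulate_observer_counts(pos, neg, observer)
    total = pos + neg
    if total == 0:
        raise UndefinedLIError("no tumour profiles counted", n_frames=n,
                               m_segments=m)
    li = 100.0 * pos / total
    ce = coefficient_error(n, m, ce_params)
    lo, hi = confidence_interval(li, ce)
    return GridCountResult(pos, neg, li, n, m, ce, lo, hi, total)


# ---------------------------------------------------------------------------
# CI-overlap agreement between observers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    """Fractions of spots whose observer confidence intervals overlap."""

    n_spots: int
    n_observers: int
    pairwise: dict = field(default_factory=dict)   # (i, j) -> fraction
    all_way: float = float("nan")

    @property
    def mean_pairwise(self) -> float:
        return float(np.mean(list(self.pairwise.values())))


def ci_agreement(results) -> AgreementReport:
    """CI-overlap agreement across observers over a list of spots.

    ``results[s]`` holds one :class:`GridCountResult` per observer for spot
    ``s``; every spot must carry the same number (>= 2) of observers.  Two
    observers agree on a spot when their intervals intersect; all observers
    agree when the common intersection is non-empty.
    """
    if not results:
        raise AlignmentError("no spots to compare")
    k = len(results[0])
    if k < 2:
        raise AlignmentError("need at least two results per spot")
    if any(len(r) != k for r in results):
        raise AlignmentError("observer lists differ in length across spots")
    pair_hits = {p: 0 for p in itertools.combinations(range(k), 2)}
    all_hits = 0
    for per_spot in results:
        ivals = [(r.ci_low_percent, r.ci_high_percent) for r in per_spot]
        for i, j in pair_hits:
            if ivals[i][0] <= ivals[j][1] and ivals[j][0] <= ivals[i][1]:
                pair_hits[(i, j)] += 1
        lo = max(v[0] for v in ivals)
        hi = min(v[1] for v in ivals)
        if lo <= hi:
            all_hits += 1
    n = len(results)
    return AgreementReport(
        n_spots=n, n_observers=k,
        pairwise={p: h / n for p, h in pair_hits.items()},
        all_way=all_hits / n)
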