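"""Synthetic TMA-spot images with exact per-cell ground truth.

This module stands in for the patient material of a Ki67 study: 1-mm tissue
microarray (TMA) cores scanned at 20x (0.5 um/px), containing tumour cell
nuclei that are either Ki67-positive (DAB brown, darker) or Ki67-negative
(hematoxylin blue, lighter), with optional stromal and lymphocytic admixture.
Every nucleus is known exactly — class, centre, radius, staining intensity —
so downstream counting and image-analysis methods can be validated against a
ground truth that real material never provides.

The per-spot true labelling index (LI) is the exact fraction of positive
tumour cells among all tumour cells; each tumour cell is positive
independently with probability ``true_li_percent / 100``, so the realized LI
fluctuates binomially around the requested one.

Determinism contract: an identical :class:`SpotSpec` (including ``seed``)
produces bit-identical truth tables, masks and rasters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._geometry import DiscFootprint, disc_footprint
from .errors import PlacementInfeasibleError, UndefinedLIError

__all__ = [
    "NormalClip", "SpotSpec", "CellProfile", "SyntheticSpot",
    "ObserverErrorModel", "tumour_mask_for", "place_nuclei", "render_spot",
    "generate_spot", "true_li", "simulate_observer_counts",
    "save_spot", "load_spot", "write_truth_csv", "read_truth_csv",
    "TUMOUR_POSITIVE", "TUMOUR_NEGATIVE", "STROMA", "LYMPHOCYTE",
    "BACKGROUND_VALUE",
]

TUMOUR_POSITIVE = "tumour_positive"
TUMOUR_NEGATIVE = "tumour_negative"
STROMA = "stroma"
LYMPHOCYTE = "lymphocyte"
CELL_CLASSES = (TUMOUR_POSITIVE, TUMOUR_NEGATIVE, STROMA, LYMPHOCYTE)

#: Base grey value of bare glass; nuclei are always rendered darker.
BACKGROUND_VALUE = 245.0

# RGB tints (added to / subtracted from the red and blue channels) that give
# DAB-stained nuclei a brown cast and hematoxylin-only nuclei a blue cast.
# The green channel is left untouched and carries the nuclear intensity.
_TINTS = {
    0: (3.0, -3.0),        # background: faintly warm glass
    1: (28.0, -30.0),      # DAB brown
    2: (-12.0, 22.0),      # hematoxylin blue
}
_CLASS_TINT = {TUMOUR_POSITIVE: 1, TUMOUR_NEGATIVE: 2, STROMA: 2, LYMPHOCYTE: 2}


@dataclass(frozen=True)
class NormalClip:
    """Normal distribution truncated (by resampling) to ``[lo, hi]``."""

    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = rng.normal(self.mean, self.sd, size)
        lo = -np.inf if self.lo is None else self.lo
        hi = np.inf if self.hi is None else self.hi
        bad = (out < lo) | (out > hi)
        # resample out-of-range draws; bounded loop to stay deterministic and finite
        for _ in range(1000):
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            out[bad] = rng.normal(self.mean, self.sd, n_bad)
            bad = (out < lo) | (out > hi)
        np.clip(out, lo, hi, out=out)
        return out


def _default_radius() -> NormalClip:
    return NormalClip(mean=5.0, sd=0.6, lo=2.5)


def _default_positive() -> NormalClip:
    return NormalClip(mean=140.0, sd=12.0, lo=95.0, hi=185.0)


def _default_negative() -> NormalClip:
    return NormalClip(mean=218.0, sd=4.0, lo=206.0, hi=228.0)


@dataclass(frozen=True)
class SpotSpec:
    """Full parameterization of one synthetic TMA spot.

    Lengths are in micrometres; densities in cells per mm^2 of the relevant
    compartment (tumour mask for tumour cells, the rest of the spot for
    stroma, the whole spot for lymphocytes); intensities on the 0-255 8-bit
    scale of the scanned image.
    """

    spot_diameter_um: float = 1000.0
    resolution_um_per_px: float = 0.5
    tumour_mask_shape: str = "disc"            # disc | blob | annulus
    tumour_mask_params: tuple[tuple[str, float], ...] = (("radius_fraction", 0.9),)
    cell_density_per_mm2: float = 2000.0
    true_li_percent: float = 30.0
    nucleus_radius_um: NormalClip = field(default_factory=_default_radius)
    overlap_allowance: float = 0.0
    positive_intensity: NormalClip = field(default_factory=_default_positive)
    negative_intensity: NormalClip = field(default_factory=_default_negative)
    stroma_cell_density_per_mm2: float = 0.0
    lymphocyte_density_per_mm2: float = 0.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.true_li_percent <= 100.0:
            raise ValueError("true_li_percent must be in [0, 100]")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if not 0.0 <= self.overlap_allowance < 1.0:
            raise ValueError("overlap_allowance must be in [0, 1)")
        if self.positive_intensity.mean >= self.negative_intensity.mean:
            raise ValueError("positive nuclei must be darker (lower mean "
                             "intensity) than negative nuclei")
        if self.tumour_mask_shape not in ("disc", "blob", "annulus"):
            raise ValueError(f"unknown tumour_mask_shape {self.tumour_mask_shape!r}")

    # -- derived geometry -----------------------------------------------------

    @property
    def image_size_px(self) -> int:
        return int(round(self.spot_diameter_um / self.resolution_um_per_px))

    @property
    def spot_radius_px(self) -> float:
        return self.image_size_px / 2.0

    @property
    def mask_params(self) -> dict[str, float]:
        return dict(self.tumour_mask_params)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SpotSpec":
        d = json.loads(text)
        for key in ("nucleus_radius_um", "positive_intensity", "negative_intensity"):
            d[key] = NormalClip(**d[key])
        d["tumour_mask_params"] = tuple(
            (k, float(v)) for k, v in d["tumour_mask_params"]
        )
        return cls(**d)


@dataclass(frozen=True)
class CellProfile:
    """Ground truth for one nuclear profile (pixel coordinates)."""

    id: int
    x: float
    y: float
    radius_px: float
    cell_class: str
    mean_intensity: float

    @property
    def is_tumour(self) -> bool:
        return self.cell_class in (TUMOUR_POSITIVE, TUMOUR_NEGATIVE)

    def footprint(self) -> DiscFootprint:
        return disc_footprint(self.x, self.y, self.radius_px)

    def boundary(self, n_vertices: int = 64) -> np.ndarray:
        """Polygonal outline, (n, 2) array of (x, y) vertices."""
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        return np.column_stack(
            (self.x + self.radius_px * np.cos(t), self.y + self.radius_px * np.sin(t))
        )


@dataclass(frozen=True)
class SyntheticSpot:
    """A rendered spot with its mask, per-cell truth and exact LI.

    ``true_li_percent`` is the realized class ratio of the truth table (not
    the requested one) and is ``None`` when the spot holds no tumour cells.
    """

    image: np.ndarray          # (H, W, 3) uint8
    tumour_mask: np.ndarray    # (H, W) bool
    truth: tuple[CellProfile, ...]
    true_li_percent: float | None
    spec: SpotSpec


@dataclass(frozen=True)
class ObserverErrorModel:
    """Imperfect human marking: missed profiles and class flips."""

    miss_prob: float = 0.0
    class_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_prob <= 1.0 or not 0.0 <= self.class_flip_prob <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# tumour mask
# ---------------------------------------------------------------------------

def _disc_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def tumour_mask_for(spec: SpotSpec) -> np.ndarray:
    """Boolean tumour-region raster for a spec (deterministic given seed).

    ``disc``: concentric disc of ``radius_fraction`` of the spot radius.
    ``annulus``: ring between ``inner_fraction`` and ``radius_fraction``.
    ``blob``: thresholded smooth random field, an irregular tumour island.
    """
    size = spec.image_size_px
    c = (size - 1) / 2.0
    r_spot = spec.spot_radius_px
    params = spec.mask_params
    frac = params.get("radius_fraction", 0.9)
    if spec.tumour_mask_shape == "disc":
        return _disc_mask(size, c, c, frac * r_spot)
    if spec.tumour_mask_shape == "annulus":
        inner = params.get("inner_fraction", 0.45)
        return _disc_mask(size, c, c, frac * r_spot) & ~_disc_mask(
            size, c, c, inner * r_spot)
    # blob: sum of a few seeded low-frequency cosine waves, thresholded
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    yy, xx = np.mgrid[:size, :size]
    fld = np.zeros((size, size))
    for _ in range(6):
        kx, ky = rng.uniform(-2.5, 2.5, 2) * 2 * np.pi / size
        ph = rng.uniform(0, 2 * np.pi)
        fld += rng.uniform(0.4, 1.0) * np.cos(kx * xx + ky * yy + ph)
    cover = params.get("coverage", 0.5)
    inside = _disc_mask(size, c, c, frac * r_spot)
    thr = np.quantile(fld[inside], 1.0 - cover)
    return inside & (fld >= thr)


# ---------------------------------------------------------------------------
# nucleus placement (hard-core point process, rejection sampled)
# ---------------------------------------------------------------------------

class _SpatialHash:
    """Uniform-grid neighbour lookup for the hard-core check."""

    def __init__(self, cell_size: float):
        self.cell = max(cell_size, 1.0)
        self.buckets: dict[tuple[int, int], list[int]] = {}
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.rs: list[float] = []

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return int(x // self.cell), int(y // self.cell)

    def conflicts(self, x: float, y: float, r: float, allowance: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for i in self.buckets.get((kx + dx, ky + dy), ()):
                    dmin = (r + self.rs[i]) * (1.0 - allowance)
                    if (x - self.xs[i]) ** 2 + (y - self.ys[i]) ** 2 < dmin * dmin:
                        return True
        return False

    def add(self, x: float, y: float, r: float) -> None:
        i = len(self.xs)
        self.xs.append(x)
        self.ys.append(y)
        self.rs.append(r)
        self.buckets.setdefault(self._key(x, y), []).append(i)


def _region_area_mm2(mask: np.ndarray, resolution: float) -> float:
    return float(mask.sum()) * resolution * resolution * 1e-6


def place_nuclei(spec: SpotSpec,
                 rng: np.random.Generator | None = None) -> list[CellProfile]:
    """Place all nuclei of a spot as a hard-core point process.

    Tumour cells land inside the tumour mask and are positive independently
    with probability ``true_li_percent/100``; stromal cells land in the
    non-tumour part of the spot; lymphocytes (smaller, hematoxylin-stained)
    anywhere in the spot.  Pairwise centre distances respect
    ``(r1 + r2) * (1 - overlap_allowance)`` across all classes.  Footprints
    stay inside the spot disc.

    Raises :class:`PlacementInfeasibleError` when the density cannot be
    realized after a bounded number of rejection-sampling attempts.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    size = spec.image_size_px
    c = (size - 1) / 2.0
    r_spot = spec.spot_radius_px
    res = spec.resolution_um_per_px
    mask = tumour_mask_for(spec)
    spot_disc = _disc_mask(size, c, c, r_spot)

    area_t = _region_area_mm2(mask, res)
    area_s = _region_area_mm2(spot_disc & ~mask, res)
    area_all = _region_area_mm2(spot_disc, res)

    n_tumour = int(round(spec.cell_density_per_mm2 * area_t))
    n_stroma = int(round(spec.stroma_cell_density_per_mm2 * area_s))
    n_lymph = int(round(spec.lymphocyte_density_per_mm2 * area_all))

    # lymphocytes: small round hematoxylin nuclei, ~55-60% of tumour radius
    lymph_radius = NormalClip(mean=0.55 * spec.nucleus_radius_um.mean,
                              sd=0.3, lo=1.5)

    plan = [
        (TUMOUR_NEGATIVE, n_tumour, mask, spec.nucleus_radius_um),
        (STROMA, n_stroma, spot_disc & ~mask, spec.nucleus_radius_um),
        (LYMPHOCYTE, n_lymph, spot_disc, lymph_radius),
    ]
    r_cap = spec.nucleus_radius_um.mean + 4 * spec.nucleus_radius_um.sd
    hash_ = _SpatialHash(2.0 * r_cap / res)

    cells: list[CellProfile] = []
    cid = 0
    for cls, target, region, radius_dist in plan:
        if target <= 0:
            continue
        ys_r, xs_r = np.nonzero(region)
        if len(xs_r) == 0:
            raise PlacementInfeasibleError(f"empty region for class {cls}")
        placed = 0
        budget = 200 * target
        while placed < target and budget > 0:
            budget -= 1
            r_um = float(radius_dist.sample(rng, 1)[0])
            r_px = r_um / res
            j = int(rng.integers(len(xs_r)))
            x = float(xs_r[j]) + float(rng.uniform(-0.5, 0.5))
            y = float(ys_r[j]) + float(rng.uniform(-0.5, 0.5))
            # footprint must stay inside the spot disc
            if (x - c) ** 2 + (y - c) ** 2 > (r_spot - r_px) ** 2:
                continue
            if hash_.conflicts(x, y, r_px, spec.overlap_allowance):
                continue
            hash_.add(x, y, r_px)
            cells.append(CellProfile(cid, x, y, r_px, cls, 0.0))
            cid += 1
            placed += 1
        if placed < target:
            raise PlacementInfeasibleError(
                f"placed {placed}/{target} {cls} cells before exhausting the "
                f"attempt budget; density infeasible under "
                f"overlap_allowance={spec.overlap_allowance}")

    # class assignment (positive vs negative) and staining intensities
    out: list[CellProfile] = []
    for cell in cells:
        cls = cell.cell_class
        if cls == TUMOUR_NEGATIVE:
            if rng.random() < spec.true_li_percent / 100.0:
                cls = TUMOUR_POSITIVE
        dist = (spec.positive_intensity if cls == TUMOUR_POSITIVE
                else spec.negative_intensity)
        out.append(replace(cell, cell_class=cls,
                           mean_intensity=float(dist.sample(rng, 1)[0])))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spot(truth: list[CellProfile] | tuple[CellProfile, ...],
                spec: SpotSpec) -> SyntheticSpot:
    """Render placed nuclei into an 8-bit RGB raster.

    Each nucleus is a filled disc at its ``mean_intensity`` on the green
    (nuclear-intensity) channel, with a class-dependent brown or blue tint on
    red/blue; where nuclei overlap the darker one wins, so confluent clumps
    merge — the failure mode high-cellularity tissue inflicts on image
    analysis.  I.i.d. Gaussian read noise of ``noise_sd`` grey levels is added
    everywhere.  Deterministic given (truth, spec).
    """
    size = spec.image_size_px
    value = np.full((size, size), BACKGROUND_VALUE)
    tint = np.zeros((size, size), dtype=np.uint8)
    for cell in truth:
        fp = cell.footprint()
        code = _CLASS_TINT[cell.cell_class]
        for k in range(fp.n_rows):
            yy = fp.y0 + k
            if not 0 <= yy < size:
                continue
            x0 = max(int(fp.xmin[k]), 0)
            x1 = min(int(fp.xmax[k]), size - 1)
            if x0 > x1:
                continue
            row = value[yy, x0:x1 + 1]
            darker = cell.mean_intensity < row
            row[darker] = cell.mean_intensity
            tint[yy, x0:x1 + 1][darker] = code

    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    g = value + noise_rng.normal(0.0, spec.noise_sd, value.shape)
    shift_r = np.array([_TINTS[i][0] for i in range(3)])[tint]
    shift_b = np.array([_TINTS[i][1] for i in range(3)])[tint]
    img = np.stack([g + shift_r, g, g + shift_b], axis=-1)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    tumour = [c for c in truth if c.is_tumour]
    li = true_li(truth) if tumour else None
    return SyntheticSpot(image=img, tumour_mask=tumour_mask_for(spec),
                         truth=tuple(truth), true_li_percent=li, spec=spec)


def generate_spot(spec: SpotSpec) -> SyntheticSpot:
    """Place and render in one step."""
    return render_spot(place_nuclei(spec), spec)


# ---------------------------------------------------------------------------
# ground-truth statistics
# ---------------------------------------------------------------------------

def true_li(truth) -> float:
    """Exact labelling index 100*P/(P+N) over tumour classes only."""
    pos = sum(1 for c in truth if c.cell_class == TUMOUR_POSITIVE)
    neg = sum(1 for c in truth if c.cell_class == TUMOUR_NEGATIVE)
    if pos + neg == 0:
        raise UndefinedLIError("no tumour cell profiles: labelling index undefined")
    return 100.0 * pos / (pos + neg)


def simulate_observer_counts(pos: int, neg: int,
                             model: ObserverErrorModel) -> tuple[int, int]:
    """Push exact (positive, negative) counts through an imperfect observer.

    Each counted profile is independently dropped with ``miss_prob`` and, if
    kept, recorded in the wrong class with ``class_flip_prob``.  Deterministic
    given ``model.seed``.
    """
    if pos < 0 or neg < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 2]))
    keep_p = int(rng.binomial(pos, 1.0 - model.miss_prob)) if pos else 0
    keep_n = int(rng.binomial(neg, 1.0 - model.miss_prob)) if neg else 0
    flip_p = int(rng.binomial(keep_p, model.class_flip_prob)) if keep_p else 0
    flip_n = int(rng.binomial(keep_n, model.class_flip_prob)) if keep_n else 0
    return keep_p - flip_p + flip_n, keep_n - flip_n + flip_p


# ---------------------------------------------------------------------------
# flat-file I/O (PNG images, CSV truth, JSON spec)
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ["id", "x", "y", "radius_px", "class", "mean_intensity"]


def write_truth_csv(truth, path) -> None:
    df = pd.DataFrame(
        [(c.id, c.x, c.y, c.radius_px, c.cell_class, c.mean_intensity)
         for c in truth],
        columns=_TRUTH_COLUMNS)
    df.to_csv(path, index=False)


def read_truth_csv(path) -> list[CellProfile]:
    df = pd.read_csv(path)
    return [CellProfile(int(r.id), float(r.x), float(r.y), float(r.radius_px),
                        str(r["class"]), float(r.mean_intensity))
            for _, r in df.iterrows()]


def save_spot(spot: SyntheticSpot, out_dir, stem: str) -> dict[str, Path]:
    """Write image (PNG RGB), mask (PNG grey), truth (CSV) and spec (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "mask": out_dir / f"{stem}_mask.png",
        "truth": out_dir / f"{stem}_truth.csv",
        "spec": out_dir / f"{stem}_spec.json",
    }
    Image.fromarray(spot.image, mode="RGB").save(paths["image"])
    Image.fromarray((spot.tumour_mask * 255).astype(np.uint8), mode="L").save(
        paths["mask"])
    write_truth_csv(spot.truth, paths["truth"])
    paths["spec"].write_text(spot.spec.to_json())
    return paths


def load_spot(out_dir, stem: str) -> SyntheticSpot:
    out_dir = Path(out_dir)
    spec = SpotSpec.from_json((out_dir / f"{stem}_spec.json").read_text())
    image = np.asarray(Image.open(out_dir / f"{stem}.png").convert("RGB"))
    mask = np.asarray(Image.open(out_dir / f"{stem}_mask.png").convert("L")) > 127
    truth = tuple(read_truth_csv(out_dir / f"{stem}_truth.csv"))
    tumour = [c for c in truth if c.is_tumour]
    li = true_li(truth) if tumour else None
    return SyntheticSpot(image=image, tumour_mask=mask, truth=truth,
                         true_li_percent=li, spec=spec)
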