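"""Section-level morphometrics of the neonatal ventricular wall.

Measurements taken on serial coronal sections: the relative area of the
expanded subventricular zone (the "Arc"), its tier decomposition, the
gyrification index (GI) of the cortical outline, thresholded positive-area
fractions (e.g. vascular smooth-muscle staining), doublecortin intensity
profiles across migratory tiers, and the serial-section (conical-frustum /
Cavalieri) volume estimator

    V = sum_{k=2..n} (A_{k-1} + A_k + sqrt(A_{k-1} A_k)) * h / 3

with section areas ``A_k`` and inter-section spacing ``h``.  The frustum sum
is exact whenever the area profile is quadratic in the section index, i.e.
for any stack of conical frusta (cylinders and cones included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull

__all__ = [
    "SectionSeries",
    "ContourSet",
    "TierSpec",
    "CorrelationResult",
    "polyline_length",
    "area_ratio",
    "tier_areas",
    "gyrification_index",
    "positive_area_fraction",
    "tier_intensity_profile",
    "estimate_volume",
    "correlate",
]


@dataclass(frozen=True)
class SectionSeries:
    """Ordered serial-section areas with inter-section spacing.

    Parameters
    ----------
    areas
        Section areas ``A_1 .. A_n`` in mm**2 (or any consistent area unit);
        all non-negative, at least two sections.
    spacing
        Distance ``h`` between consecutive sections, in mm.  Either a single
        scalar (uniform spacing, e.g. the 750 um sampling of Nissl series)
        or a sequence of ``n - 1`` per-gap distances.
    """

    areas: np.ndarray
    spacing: np.ndarray

    def __init__(self, areas: Sequence[float], spacing: float | Sequence[float]):
        areas = np.asarray(areas, dtype=float)
        if areas.ndim != 1 or areas.size < 2:
            raise ValueError("need at least two section areas")
        if np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError("section areas must be finite and non-negative")
        spacing = np.asarray(spacing, dtype=float)
        if spacing.ndim == 0:
            spacing = np.full(areas.size - 1, float(spacing))
        if spacing.size != areas.size - 1:
            raise ValueError(
                f"spacing must be scalar or length n-1={areas.size - 1}, "
                f"got {spacing.size}"
            )
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n(self) -> int:
        return int(self.areas.size)


@dataclass(frozen=True)
class ContourSet:
    """A closed cortical contour and its outer envelope.

    Both contours are closed polylines stored as ``(k, 2)`` vertex arrays
    (the closing segment back to the first vertex is implicit).  ``outer``
    may be omitted, in which case downstream code substitutes the convex
    hull of the full contour.  Generators may attach analytically known
    lengths (``full_length_true`` / ``outer_length_true``) for validation.
    """

    full: np.ndarray
    outer: np.ndarray | None = None
    full_length_true: float | None = None
    outer_length_true: float | None = None

    def __post_init__(self):
        full = np.asarray(self.full, dtype=float)
        if full.ndim != 2 or full.shape[1] != 2 or full.shape[0] < 3:
            raise ValueError("full contour must be a (k>=3, 2) vertex array")
        object.__setattr__(self, "full", full)
        if self.outer is not None:
            outer = np.asarray(self.outer, dtype=float)
            if outer.ndim != 2 or outer.shape[1] != 2 or outer.shape[0] < 3:
                raise ValueError("outer contour must be a (k>=3, 2) vertex array")
            object.__setattr__(self, "outer", outer)


@dataclass(frozen=True)
class TierSpec:
    """Rectangular box anchored at the ventricular wall, split into tiers.

    The box starts at ``origin = (row, col)`` (the wall edge), spans
    ``width`` columns, and extends away from the wall along increasing rows.
    ``offsets`` are the strictly increasing tier boundary depths in pixels:
    tier ``i`` is the band of rows ``[offsets[i-1], offsets[i])`` relative to
    the origin (with an implicit leading 0).
    """

    origin: tuple[int, int]
    width: int
    offsets: tuple[int, ...]

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("box width must be positive")
        off = tuple(int(o) for o in self.offsets)
        if len(off) < 1 or off[0] <= 0 or any(b <= a for a, b in zip(off, off[1:])):
            raise ValueError("tier offsets must be positive and strictly increasing")
        object.__setattr__(self, "offsets", off)

    @property
    def bands(self) -> list[tuple[int, int]]:
        """Tier bands as (start, stop) row offsets relative to the origin."""
        edges = (0,) + self.offsets
        return list(zip(edges[:-1], edges[1:]))


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def polyline_length(vertices: np.ndarray, closed: bool = True) -> float:
    """Total length of a polyline; closed polylines include the segment back
    to the first vertex."""
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if closed:
        length += float(np.hypot(*(v[0] - v[-1])))
    return length


def area_ratio(
    region_mask: np.ndarray,
    brain_mask: np.ndarray,
    pixel_area: float | None = None,
) -> float:
    """Region area as a percentage of total brain area on the same section.

    Both masks are boolean (or labelled; any positive label counts).  The
    per-pixel physical area cancels in the ratio; pass ``pixel_area`` only
    if you also want absolute areas, via :func:`tier_areas`.
    """
    region = np.asarray(region_mask) > 0
    brain = np.asarray(brain_mask) > 0
    if region.shape != brain.shape:
        raise ValueError("region and brain masks must share a shape")
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    if np.any(region & ~brain):
        warnings.warn("region mask extends outside the brain mask", stacklevel=2)
    return 100.0 * float(region.sum()) / n_brain


def tier_areas(
    arc_mask: np.ndarray,
    tier1_mask: np.ndarray,
    pixel_area: float = 1.0,
) -> tuple[float, float]:
    """Split the Arc area into tier 1 and tiers 2-3.

    Tier 1 is the cell-dense layer at the ventricular wall; tiers 2-3 are
    defined by subtraction: total Arc area minus tier 1.  Returns the pair
    ``(tier1_area, tiers23_area)`` in ``pixel_area`` units.
    """
    arc = np.asarray(arc_mask) > 0
    tier1 = np.asarray(tier1_mask) > 0
    if arc.shape != tier1.shape:
        raise ValueError("masks must share a shape")
    if np.any(tier1 & ~arc):
        raise ValueError("tier 1 mask must be contained in the Arc mask")
    a1 = float(tier1.sum()) * pixel_area
    a_arc = float(arc.sum()) * pixel_area
    return a1, a_arc - a1


def _hull_contour(points: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points)
    return points[hull.vertices]


def gyrification_index(contours: ContourSet) -> float:
    """Gyrification index: full contour length / outer envelope length.

    The full contour follows every sulcus and gyrus; the outer envelope
    connects the exposed cortical surface.  A smooth (convex) outline gives
    GI = 1; folding only adds length to the numerator.  When the envelope
    is not supplied it is constructed as the convex hull of the full
    contour.
    """
    outer = contours.outer
    if outer is None:
        outer = _hull_contour(contours.full)
    outer_len = polyline_length(outer)
    if outer_len <= 0:
        raise ValueError("outer contour has zero length")
    return polyline_length(contours.full) / outer_len


def positive_area_fraction(
    channel_image: np.ndarray,
    region_mask: np.ndarray,
    threshold: float | None = None,
) -> float:
    """Percent of region pixels whose intensity is strictly above threshold.

    With ``threshold=None`` the threshold is chosen automatically by the
    Renyi-entropy rule applied to the region's intensity histogram (the
    Fiji-style auto-threshold used for vascular alpha-SMA staining).
    """
    channel = np.asarray(channel_image, dtype=float)
    region = np.asarray(region_mask) > 0
    if channel.shape != region.shape:
        raise ValueError("channel and region must share a shape")
    vals = channel[region]
    if vals.size == 0:
        raise ValueError("region mask is empty")
    if threshold is None:
        from .fishquant import renyi_threshold

        threshold = renyi_threshold(vals)
    return 100.0 * float((vals > threshold).sum()) / vals.size


def tier_intensity_profile(
    channel_image: np.ndarray,
    tiers: TierSpec,
    threshold: float = 0.0,
) -> list[float]:
    """Mean positive-pixel intensity per tier band.

    For each band of the tier box, averages the intensity of pixels strictly
    above ``threshold`` (the positivity threshold applied to e.g. the DCX
    channel).  A band with no positive pixel yields ``nan`` rather than an
    error — thin or dark bands are expected near the pial end of the box.
    """
    channel = np.asarray(channel_image, dtype=float)
    r0, c0 = tiers.origin
    c1 = c0 + tiers.width
    depth = tiers.offsets[-1]
    if r0 < 0 or c0 < 0 or r0 + depth > channel.shape[0] or c1 > channel.shape[1]:
        raise ValueError("tier box does not fit inside the image")
    out: list[float] = []
    for start, stop in tiers.bands:
        band = channel[r0 + start : r0 + stop, c0:c1]
        pos = band[band > threshold]
        out.append(float(pos.mean()) if pos.size else float("nan"))
    return out


def estimate_volume(series: SectionSeries) -> float:
    """Serial-section volume by summed conical frusta.

    Each consecutive pair of sections contributes a frustum volume
    ``(A_{k-1} + A_k + sqrt(A_{k-1} A_k)) * h_k / 3``.  Exact for any solid
    whose cross-sectional area varies quadratically between sections
    (cones, cylinders, frustum stacks); for smooth solids the error shrinks
    as the section spacing is refined.
    """
    a = series.areas
    h = series.spacing
    return float(np.sum((a[:-1] + a[1:] + np.sqrt(a[:-1] * a[1:])) * h / 3.0))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Used for the across-specimen association between gyrification index and
    Arc area ratio; returns ``(r, p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
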