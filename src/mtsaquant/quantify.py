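"""Region-of-interest handling and cell-level quantification.

Regions of interest comprise cortical tubulointerstitium: inclusion polygons
minus exclusion polygons (glomeruli, arteries, capsule).  Because
inflammation directly under the renal capsule is considered non-specific,
analyses are primarily run with the subcapsular band (400 um below the
capsule) excluded.

Quantities: cell counts and densities (cells/mm2) inside the ROI, double
positivity (two detections of different markers closer than one cell
diameter count as one double-positive cell), derived populations by
geometric subtraction (e.g. CD3+CD8-), mean shortest distances between
populations, and the positive-pixel fraction of a marker plane inside the
ROI (peritubular capillary extent for CD34).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from mtsaquant.detect import Detection
from mtsaquant.unmix import ChannelPlane, ConfigurationError

logger = logging.getLogger(__name__)

SUBCAPSULAR_BAND_UM = 400.0
UM2_PER_MM2 = 1e6


@dataclass
class RegionOfInterest:
    """Cortical-tubulointerstitium ROI in global pixel coordinates.

    ``inclusions``/``exclusions`` are lists of (x, y) vertex sequences;
    ``capsule`` is a polyline along the renal capsule.  Areas are reported in
    mm2 using ``pixel_size`` (um/px).
    """

    inclusions: list[Sequence[tuple[float, float]]]
    exclusions: list[Sequence[tuple[float, float]]] = field(default_factory=list)
    capsule: Sequence[tuple[float, float]] | None = None
    pixel_size: float = 0.49

    def __post_init__(self) -> None:
        polys = [Polygon(p) for p in self.inclusions]
        for p in polys:
            if not p.is_valid:
                raise ValueError("ROI inclusion polygon is not simple/valid")
        holes = [Polygon(p) for p in self.exclusions]
        for p in holes:
            if not p.is_valid:
                raise ValueError("ROI exclusion polygon is not simple/valid")
        region = unary_union(polys)
        if holes:
            region = region.difference(unary_union(holes))
        if region.area <= 0:
            raise ValueError("ROI area must be strictly positive")
        self._region = region

    @property
    def geometry(self):
        """Shapely geometry of the effective region (inclusions minus exclusions)."""
        return self._region

    @property
    def area_mm2(self) -> float:
        return self._region.area * self.pixel_size**2 / UM2_PER_MM2

    def replace_geometry(self, geometry) -> "RegionOfInterest":
        """Clone this ROI with a precomputed shapely geometry."""
        roi = RegionOfInterest.__new__(RegionOfInterest)
        roi.inclusions = self.inclusions
        roi.exclusions = self.exclusions
        roi.capsule = self.capsule
        roi.pixel_size = self.pixel_size
        roi._region = geometry
        return roi


@dataclass(frozen=True)
class PopulationQuant:
    population: str
    count: int
    roi_area_mm2: float
    density: float  # cells per mm2


@dataclass(frozen=True)
class DistanceSummary:
    source: str
    target: str
    mean_um: float
    mean_px: float
    n_source: int
    defined: bool = True


def subcapsular_band(
    roi: RegionOfInterest, band_width_um: float = SUBCAPSULAR_BAND_UM
) -> tuple[RegionOfInterest, RegionOfInterest | None]:
    """Split an ROI into (ROI beyond the band, subcapsular band).

    The band is the part of the ROI within ``band_width_um`` Euclidean
    distance of the capsule polyline; the two outputs partition the ROI.
    The band may be None when empty (band width 0 or a remote capsule).
    """
    if roi.capsule is None:
        raise ConfigurationError("subcapsular band requested but ROI has no capsule polyline")
    if band_width_um < 0:
        raise ValueError("band width must be non-negative")
    if band_width_um == 0:
        return roi, None
    capsule = LineString(roi.capsule)
    band_geom = roi.geometry.intersection(capsule.buffer(band_width_um / roi.pixel_size))
    rest_geom = roi.geometry.difference(band_geom)
    band = roi.replace_geometry(band_geom) if band_geom.area > 0 else None
    return roi.replace_geometry(rest_geom), band


def filter_to_roi(points: Sequence, roi: RegionOfInterest) -> list:
    """Keep points inside the ROI (boundary counts as inside).

    Works for any objects with ``x``/``y`` pixel coordinates (detections or
    dot annotations).
    """
    region = roi.geometry
    return [p for p in points if region.covers(Point(p.x, p.y))]


def cell_density(points: Sequence, roi: RegionOfInterest, population: str = "") -> PopulationQuant:
    """Count points inside the ROI and convert to a density in cells/mm2."""
    area = roi.area_mm2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    inside = filter_to_roi(points, roi)
    label = population or (inside[0].marker if inside else "")
    return PopulationQuant(population=label, count=len(inside), roi_area_mm2=area,
                           density=len(inside) / area)


def _greedy_pairs(
    a_points: Sequence, b_points: Sequence, radius_um: float, pixel_size: float
) -> list[tuple[int, int, float]]:
    """One-to-one greedy ascending-distance pairing with strict distance < radius."""
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    if len(a_points) == 0 or len(b_points) == 0:
        return []
    a = np.array([(p.x, p.y) for p in a_points], dtype=np.float64) * pixel_size
    b = np.array([(p.x, p.y) for p in b_points], dtype=np.float64) * pixel_size
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    ai, bi = np.nonzero(d < radius_um)
    order = np.lexsort((bi, ai, d[ai, bi]))
    a_used = np.zeros(len(a), dtype=bool)
    b_used = np.zeros(len(b), dtype=bool)
    pairs = []
    for k in order:
        i, j = int(ai[k]), int(bi[k])
        if not a_used[i] and not b_used[j]:
            a_used[i] = b_used[j] = True
            pairs.append((i, j, float(d[i, j])))
    return pairs


def double_positive(
    dets_a: Sequence[Detection],
    dets_b: Sequence[Detection],
    radius_um: float,
    pixel_size: float,
) -> list[Detection]:
    """A-detections that pair one-to-one with a B-detection closer than radius.

    A cell is double-positive when detections of the two markers lie within
    one cell diameter (strictly less than 4 um for lymphocytes, 21 um for
    macrophages).  Pairing is one-to-one so a single B-cell cannot validate
    several A-cells.  Returns the paired A-detections relabelled A+B+.
    """
    pairs = _greedy_pairs(dets_a, dets_b, radius_um, pixel_size)
    label = ""
    if dets_a and dets_b:
        label = f"{dets_a[0].marker}+{dets_b[0].marker}+"
    return [
        Detection(x=dets_a[i].x, y=dets_a[i].y, confidence=dets_a[i].confidence,
                  marker=label or dets_a[i].marker)
        for i, _, _ in sorted(pairs)
    ]


def subtract_population(
    dets_a: Sequence[Detection],
    dets_b: Sequence[Detection],
    radius_um: float,
    pixel_size: float,
) -> list[Detection]:
    """A-detections left unpaired by :func:`double_positive` (e.g. CD3+CD8-).

    Complement of the double-positive pairing within A, so for every input
    ``len(A) == len(double_positive) + len(subtract_population)``.
    """
    paired = {i for i, _, _ in _greedy_pairs(dets_a, dets_b, radius_um, pixel_size)}
    return [d for i, d in enumerate(dets_a) if i not in paired]


def population_ratio(quant_a: PopulationQuant, quant_b: PopulationQuant) -> float:
    """Per-patient count ratio A/B; NaN (with a warning) when B is empty."""
    if quant_b.count == 0:
        logger.warning("population ratio %s/%s undefined: zero denominator",
                       quant_a.population, quant_b.population)
        return math.nan
    return quant_a.count / quant_b.count


def mean_shortest_distance(
    source: Sequence, target: Sequence, pixel_size: float,
    source_label: str = "", target_label: str = "",
) -> DistanceSummary:
    """Mean over source cells of the distance to the nearest target cell.

    Asymmetric by construction.  Flagged undefined when either population is
    empty.
    """
    if len(source) == 0 or len(target) == 0:
        return DistanceSummary(source_label, target_label, math.nan, math.nan,
                               n_source=len(source), defined=False)
    s = np.array([(p.x, p.y) for p in source], dtype=np.float64)
    t = np.array([(p.x, p.y) for p in target], dtype=np.float64)
    dists_px, _ = cKDTree(t).query(s, k=1)
    mean_px = float(np.mean(dists_px))
    return DistanceSummary(source_label, target_label, mean_px * pixel_size, mean_px,
                           n_source=len(s), defined=True)


def rasterize_roi(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the ROI on an (H, W) pixel grid."""
    mask = np.zeros(shape, dtype=bool)
    for poly in roi.inclusions:
        pts = np.array([(y, x) for x, y in poly])
        mask |= polygon2mask(shape, pts)
    for poly in roi.exclusions:
        pts = np.array([(y, x) for x, y in poly])
        mask &= ~polygon2mask(shape, pts)
    return mask


def positive_pixel_fraction(
    plane: ChannelPlane,
    roi: RegionOfInterest,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> float:
    """Percentage of ROI pixels whose plane value reaches the threshold.

    ``method='otsu'`` derives the threshold automatically from the ROI pixel
    histogram; ``method='fixed'`` uses ``fixed_threshold`` for reproducible
    reruns.  Pixels with value >= threshold count as positive.
    """
    mask = rasterize_roi(roi, plane.shape)
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("ROI does not overlap the plane")
    values = plane.abundance[mask]
    if method == "otsu":
        if np.ptp(values) == 0:
            return 0.0
        thr = threshold_otsu(values)
        positive = int((values >= thr).sum())
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        positive = int((values >= fixed_threshold).sum())
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return 100.0 * positive / n_roi
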