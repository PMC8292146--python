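"""Decoding of detector outputs into point detections.

Trained networks emit either a per-pixel probability map (semantic detectors
for lymphocytes) or a grid of box candidates with objectness scores (box
detectors for macrophages).  This module turns both into point detections:
thresholding + connected components with centroid merging for probability
maps, and greedy non-maximum suppression for box candidates.  A classical
Laplacian-of-Gaussian blob detector is provided as a deterministic reference
detector for synthetic scenes, so the decoding and evaluation contracts can
be exercised without trained weights.

Decoding thresholds used in the study: 0.7 for the strongly stained CD3
channel and 0.4 for the other cytoplasmic lymphocyte channels; 0.4 for
nuclear lymphocyte markers; objectness 0.45 with overlap threshold 0.05 for
macrophage boxes.  Lymphocyte maps are decoded at 0.49 um/px, macrophage
boxes at 0.98 um/px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max

from mtsaquant.unmix import ChannelPlane

#: decoding resolutions, um per pixel
LYMPHOCYTE_PIXEL_SIZE_UM = 0.49
MACROPHAGE_PIXEL_SIZE_UM = 0.98

#: cell-diameter defaults, um
LYMPHOCYTE_DIAMETER_UM = 4.0
MACROPHAGE_DIAMETER_UM = 21.0

#: decoding thresholds
CD3_THRESHOLD = 0.7
LYMPHOCYTE_THRESHOLD = 0.4
MACROPHAGE_OBJECTNESS_THRESHOLD = 0.45
MACROPHAGE_NMS_OVERLAP = 0.05


@dataclass(frozen=True)
class Detection:
    """A point detection in global pixel coordinates (sub-pixel allowed)."""

    x: float
    y: float
    confidence: float = 1.0
    marker: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("detection coordinates must be finite")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class BoxCandidate:
    """A square box candidate from a box-grid detector."""

    x: float
    y: float
    side: float
    objectness: float

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("box side must be positive")


def decode_probability_map(
    prob: np.ndarray,
    threshold: float,
    min_separation_um: float,
    pixel_size: float = LYMPHOCYTE_PIXEL_SIZE_UM,
    marker: str = "",
) -> list[Detection]:
    """Decode a probability map into point detections.

    Pixels with probability >= threshold are grouped into connected
    components (8-connectivity).  Components whose centroids lie closer than
    ``min_separation_um`` are merged (transitively); each resulting group
    yields one detection at the centroid of its combined pixels, with
    confidence equal to the group's maximum probability.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if not np.all(np.isfinite(prob)):
        raise ValueError("probability map contains non-finite values")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mask = prob >= threshold
    if not mask.any():
        return []
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    idx = np.arange(1, n + 1)
    centroids = np.array(ndi.center_of_mass(mask, labels, idx))  # (n, 2) as (row, col)
    sizes = ndi.sum_labels(mask, labels, idx)
    maxima = ndi.maximum(prob, labels, idx)

    # transitive merge of components with close centroids (union-find)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    min_sep_px = min_separation_um / pixel_size
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    for i, j in zip(*np.nonzero(np.triu(d < min_sep_px, k=1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    detections = []
    for members in groups.values():
        m = np.array(members)
        w = sizes[m]
        cy, cx = (centroids[m] * w[:, None]).sum(axis=0) / w.sum()
        detections.append(Detection(x=float(cx), y=float(cy),
                                    confidence=float(maxima[m].max()), marker=marker))
    detections.sort(key=lambda det: (det.y, det.x))
    return detections


def _iou(a: BoxCandidate, b: BoxCandidate) -> float:
    ax0, ax1 = a.x - a.side / 2, a.x + a.side / 2
    ay0, ay1 = a.y - a.side / 2, a.y + a.side / 2
    bx0, bx1 = b.x - b.side / 2, b.x + b.side / 2
    by0, by1 = b.y - b.side / 2, b.y + b.side / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.side**2 + b.side**2 - inter
    return inter / union if union > 0 else 0.0


def non_maximum_suppression(
    candidates: list[BoxCandidate],
    objectness_threshold: float = MACROPHAGE_OBJECTNESS_THRESHOLD,
    overlap_threshold: float = MACROPHAGE_NMS_OVERLAP,
    marker: str = "",
) -> list[Detection]:
    """Greedy non-maximum suppression of box candidates.

    Candidates below ``objectness_threshold`` are dropped.  Survivors are
    taken in descending objectness (ties broken by (y, x) lexicographic
    order); each kept box suppresses remaining candidates whose
    intersection-over-union with it exceeds ``overlap_threshold``.
    """
    if not 0.0 <= objectness_threshold <= 1.0:
        raise ValueError("objectness_threshold must be in [0, 1]")
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in [0, 1]")
    alive = sorted(
        (c for c in candidates if c.objectness >= objectness_threshold),
        key=lambda c: (-c.objectness, c.y, c.x),
    )
    kept: list[BoxCandidate] = []
    while alive:
        best = alive.pop(0)
        kept.append(best)
        alive = [c for c in alive if _iou(best, c) <= overlap_threshold]
    return [Detection(x=c.x, y=c.y, confidence=c.objectness, marker=marker) for c in kept]


def reference_blob_detector(
    plane: ChannelPlane,
    cell_radius_um: float,
    relative_threshold: float = 0.1,
    marker: str | None = None,
) -> list[Detection]:
    """Scale-matched Laplacian-of-Gaussian blob detector.

    Detects bright blobs of radius ``cell_radius_um`` using a negated LoG
    filter at sigma = radius / sqrt(2) (the scale at which the LoG response of
    a blob of that radius peaks) and returns local maxima whose response is at
    least ``relative_threshold`` times the global maximum response.  Serves
    as a deterministic stand-in detector on synthetic scenes.
    """
    if cell_radius_um <= 0:
        raise ValueError("cell radius must be positive")
    img = plane.abundance.astype(np.float64)
    if img.size == 0 or img.max() <= 0:
        return []
    sigma_px = cell_radius_um / plane.pixel_size / np.sqrt(2.0)
    response = -ndi.gaussian_laplace(img, sigma=sigma_px)
    peak = response.max()
    if peak <= 0:
        return []
    min_dist = max(1, int(round(cell_radius_um / plane.pixel_size)))
    coords = peak_local_max(
        response,
        min_distance=min_dist,
        threshold_abs=relative_threshold * peak,
        exclude_border=False,
    )
    label = marker if marker is not None else plane.marker
    x0, y0 = plane.origin
    dets = [
        Detection(x=float(c + x0), y=float(r + y0),
                  confidence=float(min(1.0, response[r, c] / peak)), marker=label)
        for r, c in coords
    ]
    dets.sort(key=lambda det: (det.y, det.x))
    return dets
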