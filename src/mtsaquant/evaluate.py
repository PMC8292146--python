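"""Matching detections to dot annotations and scoring precision/recall/F1.

A detection counts as true positive when it lies within one average cell
diameter of a ground-truth annotation (4 um for lymphocytes, 21 um for
macrophages).  When several detections fall within range of one annotation,
only the closest detection is credited; the rule is realized as a global
greedy one-to-one assignment over all (detection, annotation) pairs in
ascending distance order, which is deterministic and reproduces the stated
closest-detection tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from mtsaquant.asap import DotAnnotation
from mtsaquant.detect import Detection


@dataclass
class MatchResult:
    """One-to-one matching outcome between detections and annotations.

    Invariants: ``tp == len(pairs)``, ``tp + fn == n annotations``,
    ``tp + fp == n detections``; every paired distance <= radius.
    """

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (det idx, ann idx, distance um)


@dataclass(frozen=True)
class PRF1Score:
    precision: float
    recall: float
    f1: float


def _xy(points: Sequence) -> np.ndarray:
    if len(points) == 0:
        return np.empty((0, 2), dtype=np.float64)
    return np.array([(p.x, p.y) for p in points], dtype=np.float64)


def match_detections(
    detections: Sequence[Detection],
    annotations: Sequence[DotAnnotation],
    radius_um: float,
    pixel_size: float,
    strict: bool = False,
) -> MatchResult:
    """Greedily match detections to annotations within a radius.

    All (detection, annotation) pairs with distance <= radius (or < radius
    when ``strict``) are sorted by ascending distance, ties broken by
    (annotation index, detection index), and assigned one-to-one in that
    order.  Unassigned detections are false positives; unassigned annotations
    are false negatives.  Coordinates are pixels; radius is micrometres.
    """
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    det_xy = _xy(detections) * pixel_size
    ann_xy = _xy(annotations) * pixel_size
    if len(det_xy) == 0 or len(ann_xy) == 0:
        return MatchResult(tp=0, fp=len(det_xy), fn=len(ann_xy))
    d = np.linalg.norm(det_xy[:, None, :] - ann_xy[None, :, :], axis=-1)
    within = d < radius_um if strict else d <= radius_um
    di, ai = np.nonzero(within)
    order = np.lexsort((di, ai, d[di, ai]))
    det_used = np.zeros(len(det_xy), dtype=bool)
    ann_used = np.zeros(len(ann_xy), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(di[k]), int(ai[k])
        if not det_used[i] and not ann_used[j]:
            det_used[i] = ann_used[j] = True
            pairs.append((i, j, float(d[i, j])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(det_xy) - tp, fn=len(ann_xy) - tp, pairs=pairs)


def prf1(tp: int, fp: int, fn: int) -> PRF1Score:
    """Precision, recall and F1 from counts; any 0/0 ratio is defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return PRF1Score(precision=p, recall=r, f1=f1)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_slide_set(
    slides: Iterable[tuple[Sequence[Detection], Sequence[DotAnnotation]]],
    radius_by_marker: dict[str, float],
    pixel_size: float,
    strict: bool = False,
) -> tuple[list[dict], dict]:
    """Score a test set of slides per marker, per slide and pooled.

    Each slide contributes detections and annotations; they are grouped by
    marker label, matched with the marker's radius, and scored.  Pooled
    scores are computed from summed TP/FP/FN across slides, not by averaging
    per-slide scores.

    Returns (per-slide rows, pooled rows keyed by marker).  Raises if a
    slide contains a marker with no configured radius.
    """
    per_slide: list[dict] = []
    pooled: dict[str, dict] = {}
    for slide_idx, (dets, anns) in enumerate(slides):
        markers = sorted({d.marker for d in dets} | {a.marker for a in anns})
        for marker in markers:
            if marker not in radius_by_marker:
                raise KeyError(f"no matching radius configured for marker {marker!r}")
            m_dets = [d for d in dets if d.marker == marker]
            m_anns = [a for a in anns if a.marker == marker]
            res = match_detections(m_dets, m_anns, radius_by_marker[marker], pixel_size, strict)
            score = prf1(res.tp, res.fp, res.fn)
            per_slide.append({
                "slide": slide_idx, "marker": marker,
                "tp": res.tp, "fp": res.fp, "fn": res.fn,
                "precision": score.precision, "recall": score.recall, "f1": score.f1,
            })
            agg = pooled.setdefault(marker, {"tp": 0, "fp": 0, "fn": 0})
            agg["tp"] += res.tp
            agg["fp"] += res.fp
            agg["fn"] += res.fn
    for marker, agg in pooled.items():
        score = prf1(agg["tp"], agg["fp"], agg["fn"])
        agg.update(precision=score.precision, recall=score.recall, f1=score.f1)
    return per_slide, pooled
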