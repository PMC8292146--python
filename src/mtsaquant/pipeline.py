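"""End-to-end pipeline over synthetic scenes.

Chains the full workflow on a ground-truthed scene: render multispectral
tiles, unmix them against the spectral library, stitch per-fluorophore
whole-slide planes, convert each marker plane plus DAPI to artificial
brightfield IHC, recover the marker signal by colour deconvolution, run the
reference blob detector, and score detections and densities against the
planted ground truth.  This is the harness used to validate the pipeline in
the absence of the original biopsy images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mtsaquant import brightfield as bf
from mtsaquant.detect import reference_blob_detector
from mtsaquant.evaluate import match_detections, prf1
from mtsaquant.quantify import cell_density, double_positive, positive_pixel_fraction
from mtsaquant.synthetic import RenderConfig, SceneGroundTruth, cell_class, render_multispectral
from mtsaquant.unmix import ChannelPlane, stitch_planes, unmix_tile


@dataclass
class PopulationResult:
    marker: str
    n_truth: int
    n_detected: int
    precision: float
    recall: float
    f1: float
    density_truth: float
    density_detected: float

    @property
    def density_rel_error(self) -> float:
        if self.density_truth == 0:
            return 0.0 if self.density_detected == 0 else np.inf
        return abs(self.density_detected - self.density_truth) / self.density_truth


def stitched_marker_planes(
    scene: SceneGroundTruth, cfg: RenderConfig, tile_size: int = 256
) -> dict[str, ChannelPlane]:
    """Render -> unmix -> stitch; returns whole-slide planes keyed by marker."""
    tiles = render_multispectral(scene, cfg, tile_size)
    unmixed = [unmix_tile(t, cfg.library) for t in tiles]
    H, W = scene.shape_px
    planes: dict[str, ChannelPlane] = {}
    for fluor in cfg.library.fluorophores:
        tile_planes = [p for per_tile in unmixed for p in per_tile if p.fluorophore == fluor]
        planes[cfg.library.marker_for(fluor)] = stitch_planes(tile_planes, (W, H))
    return planes


def detect_from_brightfield(
    image: bf.BrightfieldImage,
    pixel_size: float,
    cell_radius_um: float,
    relative_threshold: float = 0.2,
):
    """Recover the DAB signal from a brightfield image and run the blob detector.

    The marker intensity is recovered by least-squares colour deconvolution of
    the (pre-quantization, if available) RGB image against the stain vectors;
    the blob detector then runs at the scale of a Gaussian cell of the given
    radius (filter sigma = radius / 2).
    """
    rgb = image.rgb_float if image.rgb_float is not None else image.rgb
    _, i_ihc = bf.invert_brightfield(rgb, image.hematoxylin, image.dab)
    plane = ChannelPlane(np.clip(i_ihc, 0, None), image.marker, image.marker,
                         pixel_size=pixel_size)
    return reference_blob_detector(
        plane, cell_radius_um / np.sqrt(2.0), relative_threshold, marker=image.marker
    )


def run_end_to_end(
    scene: SceneGroundTruth,
    cfg: RenderConfig,
    tile_size: int = 256,
    relative_threshold: float = 0.2,
) -> dict:
    """Full synthetic validation run.

    Returns per-population detection scores and density recovery, planted vs
    recovered double-positive counts (from ground-truth coordinates), and the
    capillary positive-pixel percentage against its planted fraction.
    """
    planes = stitched_marker_planes(scene, cfg, tile_size)
    images = bf.assemble_pairs(planes, "DAPI", scale_max=1.0, keep_float=True)
    roi = scene.roi()
    results: dict[str, PopulationResult] = {}
    for marker, image in images:
        gts = scene.dots(marker)
        if marker == "AF" or marker == "CD34" or not gts:
            continue
        radius_um = cfg.cell_radius_um[cell_class(frozenset({marker}))]
        dets = detect_from_brightfield(image, scene.pixel_size, radius_um / 2.0,
                                       relative_threshold)
        match = match_detections(dets, gts, radius_um, scene.pixel_size)
        score = prf1(match.tp, match.fp, match.fn)
        results[marker] = PopulationResult(
            marker=marker,
            n_truth=len(gts),
            n_detected=len(dets),
            precision=score.precision,
            recall=score.recall,
            f1=score.f1,
            density_truth=cell_density(gts, roi, marker).density,
            density_detected=cell_density(dets, roi, marker).density,
        )

    coloc: dict[tuple[str, str], tuple[int, int]] = {}
    markers = sorted({m for c in scene.cells for m in c.markers if m != "DAPI"})
    for a in markers:
        for b in markers:
            if a >= b:
                continue
            planted = len(scene.cells_with(a, b))
            if planted == 0:
                continue
            radius = max(
                cfg.cell_radius_um[cell_class(frozenset({a}))],
                cfg.cell_radius_um[cell_class(frozenset({b}))],
            )
            recovered = len(
                double_positive(scene.detections(a), scene.detections(b),
                                radius, scene.pixel_size)
            )
            coloc[(a, b)] = (planted, recovered)

    capillary = None
    if scene.capillary_mask.any() and "CD34" in planes:
        capillary = {
            "planted_pct": 100.0 * scene.capillary_fraction,
            "measured_pct": positive_pixel_fraction(planes["CD34"], roi, method="otsu"),
        }

    return {"populations": results, "coloc": coloc, "capillary": capillary}
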