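"""Ground-truthed synthetic scenes rendered into every pipeline input format.

A scene is a rectangular patch of virtual cortex: cells with known marker
memberships (drawn from the two staining panels), a capillary mask with a
known positive-area fraction (standing in for CD34+ peritubular capillaries),
an ROI polygon and a capsule polyline.  Scenes are rendered through a known
spectral library into multispectral tiles — optionally with band-wise
Gaussian noise and fluorophore cross-talk (emulating bleed-through of a
strong CD68 signal into the CD4 channel) — so unmixing, stitching,
brightfield conversion, detection and quantification can all be validated
against planted ground truth.

Cells are isotropic Gaussian intensity bumps with sigma = radius / 2, placed
uniformly inside the ROI with a minimum center separation of one cell radius;
double-positive cells are planted exactly: round(fraction * population size)
members of population A also carry marker B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from mtsaquant.asap import AsapAnnotation, DotAnnotation, write_asap_xml
from mtsaquant.detect import Detection
from mtsaquant.quantify import RegionOfInterest, rasterize_roi
from mtsaquant.unmix import DEFAULT_PIXEL_SIZE_UM, ConfigurationError, MultispectralTile, SpectralLibrary

PANEL_VOCABULARY = ("CD3", "CD4", "CD8", "CD20", "CD68", "CD34", "Tbet", "GATA3", "CD163", "DAPI")
MACROPHAGE_MARKERS = frozenset({"CD68", "CD163"})

#: default cell radii per class, um
CELL_RADIUS_UM = {"lymphocyte": 4.0, "macrophage": 21.0}


def cell_class(markers: frozenset[str]) -> str:
    return "macrophage" if markers & MACROPHAGE_MARKERS else "lymphocyte"


@dataclass(frozen=True)
class Cell:
    x_um: float
    y_um: float
    markers: frozenset[str]


@dataclass
class SceneGroundTruth:
    """A generated scene with complete ground truth."""

    cells: list[Cell]
    capillary_mask: np.ndarray  # bool, H x W at scene pixel grid
    capillary_fraction: float  # planted positive fraction of ROI pixels
    roi_polygons: list[list[tuple[float, float]]]  # px
    capsule_polyline: list[tuple[float, float]]  # px
    scene_size_um: tuple[float, float]
    pixel_size: float
    seed: int

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.scene_size_um
        return int(round(h / self.pixel_size)), int(round(w / self.pixel_size))

    def roi(self) -> RegionOfInterest:
        return RegionOfInterest(
            inclusions=self.roi_polygons,
            capsule=self.capsule_polyline,
            pixel_size=self.pixel_size,
        )

    def cells_with(self, *markers: str) -> list[Cell]:
        want = set(markers)
        return [c for c in self.cells if want <= c.markers]

    def dots(self, marker: str) -> list[DotAnnotation]:
        """Ground-truth dot annotations for one marker, in pixel coordinates."""
        return [
            DotAnnotation(x=c.x_um / self.pixel_size, y=c.y_um / self.pixel_size, marker=marker)
            for c in self.cells_with(marker)
        ]

    def detections(self, marker: str) -> list[Detection]:
        """Ground-truth positions re-typed as detections (for co-localization tests)."""
        return [
            Detection(x=c.x_um / self.pixel_size, y=c.y_um / self.pixel_size, marker=marker)
            for c in self.cells_with(marker)
        ]


@dataclass
class RenderConfig:
    """How a scene is turned into multispectral tiles."""

    library: SpectralLibrary
    brightness: dict[str, float] = field(default_factory=dict)  # per marker, default 1.0
    noise_sd: float = 0.0  # additive band-wise Gaussian, clipped at 0
    bleed_matrix: np.ndarray | None = None  # fluorophore x fluorophore cross-talk
    cell_radius_um: dict[str, float] = field(default_factory=lambda: dict(CELL_RADIUS_UM))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bleed_matrix is not None:
            m = np.asarray(self.bleed_matrix, dtype=np.float64)
            nf = len(self.library.fluorophores)
            if m.shape != (nf, nf):
                raise ValueError(f"bleed matrix must be {nf}x{nf}")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("bleed matrix diagonal must be 1")
            off = m[~np.eye(nf, dtype=bool)]
            if np.any(off < 0) or np.any(off >= 1):
                raise ValueError("cross-talk weights must lie in [0, 1)")
            self.bleed_matrix = m


def default_spectral_library(panel: int = 2, n_bands: int = 30) -> SpectralLibrary:
    """Synthetic emission library: one Gaussian profile per fluorophore.

    Emulates a DAPI + Opal-series + autofluorescence library across
    ``n_bands`` acquisition bands, with the antibody-fluorophore assignment
    of panel I (CD3/CD4/CD8/CD20/CD68/CD34) or panel II
    (CD4/Tbet/GATA3/CD68/CD163).  Peaks are spread across the band axis so
    the library matrix has full column rank.
    """
    if panel == 1:
        marker_map = {
            "DAPI": "DAPI", "Opal520": "CD4", "Opal540": "CD68", "Opal570": "CD8",
            "Opal620": "CD20", "Opal650": "CD3", "Opal690": "CD34",
        }
    elif panel == 2:
        marker_map = {
            "DAPI": "DAPI", "Opal520": "CD4", "Opal540": "CD68", "Opal570": "Tbet",
            "Opal620": "GATA3", "Opal650": "CD163",
        }
    else:
        raise ValueError("panel must be 1 or 2")
    fluors = tuple(marker_map) + ("AF",)
    bands = np.arange(n_bands, dtype=np.float64)
    peaks = np.linspace(2.0, n_bands - 3.0, len(fluors))
    width = (peaks[1] - peaks[0]) * 0.55
    spectra = np.exp(-0.5 * ((bands[None, :] - peaks[:, None]) / width) ** 2)
    return SpectralLibrary(fluors, spectra, marker_map)


def generate_scene(
    n_cells_per_population: dict[str, int],
    coloc_fractions: dict[tuple[str, str], float] | None = None,
    scene_size_um: float | tuple[float, float] = 500.0,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    capillary_fraction: float = 0.08,
    roi_margin_um: float = 25.0,
    cell_radius_um: dict[str, float] | None = None,
) -> SceneGroundTruth:
    """Generate a ground-truthed scene.

    Parameters
    ----------
    n_cells_per_population
        Cells per primary population, keyed by marker (e.g. ``{"CD68": 40}``).
    coloc_fractions
        Map (A, B) -> fraction of the A population that also carries B; the
        planted double-positive count is ``round(fraction * n_A)`` exactly.
    scene_size_um
        Scene width/height in micrometres (scalar for a square scene).
    capillary_fraction
        Planted CD34+ positive-area fraction of the ROI.
    roi_margin_um
        Inset of the rectangular ROI from the scene border; the capsule
        polyline runs along the top ROI edge.

    The same seed reproduces the identical scene bit-for-bit.
    """
    coloc_fractions = coloc_fractions or {}
    radii = dict(CELL_RADIUS_UM)
    if cell_radius_um:
        radii.update(cell_radius_um)
    for marker, n in n_cells_per_population.items():
        if n < 0:
            raise ValueError(f"negative cell count for {marker}")
        if marker not in PANEL_VOCABULARY:
            raise ValueError(f"unknown marker {marker!r}")
    for (a, b), f in coloc_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"co-localization fraction for ({a},{b}) outside [0, 1]: {f}")
    if not 0.0 <= capillary_fraction <= 1.0:
        raise ValueError("capillary_fraction must lie in [0, 1]")
    if np.isscalar(scene_size_um):
        scene_size_um = (float(scene_size_um), float(scene_size_um))
    w_um, h_um = scene_size_um
    if w_um <= 0 or h_um <= 0:
        raise ValueError("scene size must be positive")

    rng = np.random.default_rng(seed)
    m = roi_margin_um / pixel_size
    w_px, h_px = w_um / pixel_size, h_um / pixel_size
    roi_poly = [(m, m), (w_px - m, m), (w_px - m, h_px - m), (m, h_px - m)]
    capsule = [(m, m), (w_px - m, m)]

    # place populations, largest cells first so separation constraints are satisfiable
    placed: list[tuple[float, float, float]] = []  # (x_um, y_um, radius_um)
    cells_by_pop: dict[str, list[Cell]] = {}
    lo_x, hi_x = roi_margin_um, w_um - roi_margin_um
    lo_y, hi_y = roi_margin_um, h_um - roi_margin_um
    populations = sorted(
        n_cells_per_population, key=lambda mk: -radii[cell_class(frozenset({mk}))]
    )
    for marker in populations:
        n = n_cells_per_population[marker]
        r = radii[cell_class(frozenset({marker}))]
        pop: list[Cell] = []
        attempts = 0
        while len(pop) < n:
            attempts += 1
            if attempts > 10000 * max(n, 1):
                raise RuntimeError(f"cannot place {n} {marker} cells in {scene_size_um} um scene")
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if all((x - px) ** 2 + (y - py) ** 2 >= max(r, pr) ** 2 for px, py, pr in placed):
                placed.append((x, y, r))
                pop.append(Cell(x, y, frozenset({marker, "DAPI"})))
        cells_by_pop[marker] = pop

    # plant double positives: exactly round(fraction * |A|) A-cells also carry B
    for (a, b), f in sorted(coloc_fractions.items()):
        pop = cells_by_pop.get(a, [])
        k = int(round(f * len(pop)))
        chosen = rng.choice(len(pop), size=k, replace=False) if k else []
        for i in sorted(int(i) for i in np.atleast_1d(chosen)):
            c = pop[i]
            pop[i] = Cell(c.x_um, c.y_um, c.markers | {b})

    cells = [c for marker in populations for c in cells_by_pop[marker]]

    # capillary mask: smoothed random field thresholded inside the ROI so the
    # positive fraction of ROI pixels matches the request exactly
    shape = (int(round(h_px)), int(round(w_px)))
    mask = np.zeros(shape, dtype=bool)
    if capillary_fraction > 0:
        roi_mask = rasterize_roi(
            RegionOfInterest([roi_poly], pixel_size=pixel_size), shape
        )
        fld = gaussian_filter(rng.standard_normal(shape), sigma=8.0 / pixel_size)
        vals = fld[roi_mask]
        k = int(round(capillary_fraction * vals.size))
        if k > 0:
            thr = np.partition(vals, vals.size - k)[vals.size - k]
            mask = roi_mask & (fld >= thr)

    return SceneGroundTruth(
        cells=cells,
        capillary_mask=mask,
        capillary_fraction=capillary_fraction,
        roi_polygons=[roi_poly],
        capsule_polyline=capsule,
        scene_size_um=(w_um, h_um),
        pixel_size=pixel_size,
        seed=seed,
    )


def _add_gaussian(plane: np.ndarray, cx_px: float, cy_px: float, sigma_px: float, amp: float) -> None:
    h, w = plane.shape
    r = int(np.ceil(4 * sigma_px))
    x0, x1 = max(0, int(cx_px) - r), min(w, int(cx_px) + r + 1)
    y0, y1 = max(0, int(cy_px) - r), min(h, int(cy_px) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amp * np.exp(
        -((xs - cx_px) ** 2 + (ys - cy_px) ** 2) / (2 * sigma_px**2)
    )


def render_abundances(scene: SceneGroundTruth, cfg: RenderConfig) -> dict[str, np.ndarray]:
    """Per-fluorophore abundance planes (before cross-talk and noise).

    Each cell contributes a Gaussian bump of sigma = radius / 2 and peak
    amplitude equal to the marker brightness to the plane of every
    fluorophore whose mapped marker it carries; the capillary mask feeds the
    CD34 plane.  Fluorophores mapped to no rendered marker (autofluorescence)
    stay zero.
    """
    shape = scene.shape_px
    planes = {f: np.zeros(shape, dtype=np.float64) for f in cfg.library.fluorophores}
    marker_to_fluor = {cfg.library.marker_for(f): f for f in cfg.library.fluorophores}
    for cell in scene.cells:
        sigma_px = cfg.cell_radius_um[cell_class(cell.markers)] / 2.0 / scene.pixel_size
        cx, cy = cell.x_um / scene.pixel_size, cell.y_um / scene.pixel_size
        for marker in cell.markers:
            fluor = marker_to_fluor.get(marker)
            if fluor is None:
                continue
            amp = cfg.brightness.get(marker, 1.0)
            _add_gaussian(planes[fluor], cx, cy, sigma_px, amp)
    cd34_fluor = marker_to_fluor.get("CD34")
    if cd34_fluor is not None and scene.capillary_mask.any():
        planes[cd34_fluor] += cfg.brightness.get("CD34", 1.0) * scene.capillary_mask
    return planes


def render_multispectral(
    scene: SceneGroundTruth, cfg: RenderConfig, tile_size: int = 256
) -> list[MultispectralTile]:
    """Render a scene into multispectral tiles with stored origins.

    The pixel spectrum is the linear combination of library spectra weighted
    by the (cross-talk mixed) abundances, plus optional additive Gaussian
    noise clipped at zero.  Tiles partition the scene; edge tiles are
    truncated.  Deterministic for a fixed scene and configuration (the noise
    stream derives from the scene seed).
    """
    if tile_size <= 0:
        raise ValueError("tile size must be positive")
    lib = cfg.library
    planes = render_abundances(scene, cfg)
    abund = np.stack([planes[f] for f in lib.fluorophores], axis=-1)  # H x W x F
    if cfg.bleed_matrix is not None:
        abund = abund @ cfg.bleed_matrix  # source fluorophore rows -> observed columns
    cube = abund @ lib.spectra  # H x W x B
    if cfg.noise_sd > 0:
        noise_rng = np.random.default_rng([scene.seed, 202])
        cube = cube + noise_rng.normal(0.0, cfg.noise_sd, size=cube.shape)
    cube = np.clip(cube, 0.0, None)
    H, W, _ = cube.shape
    tiles = []
    for y0 in range(0, H, tile_size):
        for x0 in range(0, W, tile_size):
            tiles.append(
                MultispectralTile(
                    intensities=cube[y0:y0 + tile_size, x0:x0 + tile_size],
                    origin=(x0, y0),
                    pixel_size=scene.pixel_size,
                )
            )
    return tiles


def write_annotations(scene: SceneGroundTruth, path) -> None:
    """Write the scene's dots, ROI polygons and capsule as ASAP XML."""
    anns: list[AsapAnnotation] = []
    for i, cell in enumerate(scene.cells):
        for marker in sorted(cell.markers - {"DAPI"}):
            anns.append(
                AsapAnnotation(
                    name=f"cell_{i}_{marker}", atype="Dot", group=marker,
                    coordinates=[(cell.x_um / scene.pixel_size, cell.y_um / scene.pixel_size)],
                )
            )
    for j, poly in enumerate(scene.roi_polygons):
        anns.append(AsapAnnotation(name=f"cortex_{j}", atype="Polygon", group="cortex",
                                   coordinates=list(poly)))
    if scene.capsule_polyline:
        anns.append(AsapAnnotation(name="capsule", atype="PointSet", group="capsule",
                                   coordinates=list(scene.capsule_polyline)))
    write_asap_xml(path, anns)


def write_ground_truth(scene: SceneGroundTruth, path) -> None:
    """JSON sidecar with the full ground truth (cells in um, planted fractions)."""
    payload = {
        "seed": scene.seed,
        "pixel_size": scene.pixel_size,
        "scene_size_um": list(scene.scene_size_um),
        "capillary_fraction": scene.capillary_fraction,
        "roi_polygons": [[list(v) for v in p] for p in scene.roi_polygons],
        "capsule_polyline": [list(v) for v in scene.capsule_polyline],
        "cells": [
            {"x_um": c.x_um, "y_um": c.y_um, "markers": sorted(c.markers)} for c in scene.cells
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
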