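"""Spectral unmixing of multispectral tiles and stitching of unmixed planes.

A multispectral acquisition records, per pixel, intensities across B narrow
acquisition bands.  Under the linear mixing model each pixel spectrum is a
non-negative combination of the emission spectra of the fluorophores present
in the panel (plus a constant autofluorescence spectrum).  Given a spectral
library of those per-fluorophore emission profiles, unmixing recovers the
per-fluorophore abundance at every pixel by non-negative least squares.

Tiles carry their global origin (the scanner's stored coordinates), so the
unmixed single-fluorophore planes can be stitched back into whole-slide
planes by pasting each tile at its origin.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

logger = logging.getLogger(__name__)

#: default pixel size of the multispectral acquisition, in micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.49


class ConfigurationError(ValueError):
    """Invalid library / panel configuration."""


@dataclass(frozen=True)
class SpectralLibrary:
    """Per-fluorophore emission weights across acquisition bands.

    Parameters
    ----------
    fluorophores
        Ordered fluorophore labels (e.g. ``("DAPI", "Opal520", ..., "AF")``).
    spectra
        Array of shape (n_fluorophores, n_bands); each row is one emission
        profile.  Rows are max-normalized to 1 on construction so that
        abundance units follow pixel intensity units.
    marker_map
        Optional mapping fluorophore label -> antibody/marker label.
    """

    fluorophores: tuple[str, ...]
    spectra: np.ndarray
    marker_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spectra = np.asarray(self.spectra, dtype=np.float64)
        if spectra.ndim != 2 or spectra.shape[0] != len(self.fluorophores):
            raise ConfigurationError(
                f"spectra shape {spectra.shape} does not match "
                f"{len(self.fluorophores)} fluorophores"
            )
        if spectra.shape[0] == 0:
            raise ConfigurationError("spectral library is empty")
        if np.any(spectra < 0):
            raise ConfigurationError("emission weights must be non-negative")
        peaks = spectra.max(axis=1)
        if np.any(peaks <= 0):
            raise ConfigurationError("every spectrum must have a positive peak")
        object.__setattr__(self, "spectra", spectra / peaks[:, None])
        if np.linalg.matrix_rank(self.spectra) < len(self.fluorophores):
            raise ConfigurationError("spectral library matrix is rank-deficient")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def marker_for(self, fluorophore: str) -> str:
        return self.marker_map.get(fluorophore, fluorophore)

    def to_json(self, path) -> None:
        payload = {
            "fluorophores": {f: self.spectra[i].tolist() for i, f in enumerate(self.fluorophores)},
            "marker_map": self.marker_map,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SpectralLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        fluors = tuple(payload["fluorophores"])
        spectra = np.array([payload["fluorophores"][f] for f in fluors], dtype=np.float64)
        return cls(fluors, spectra, payload.get("marker_map", {}))


@dataclass
class MultispectralTile:
    """Raw H x W x B tile with its global origin in pixels."""

    intensities: np.ndarray
    origin: tuple[int, int]  # (x, y) global pixel coordinates
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("tile intensities must be H x W x B")
        if np.any(self.intensities < 0):
            raise ValueError("tile intensities must be non-negative")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("tile origin must be non-negative")


@dataclass
class ChannelPlane:
    """Unmixed single-fluorophore abundance plane (H x W, float32)."""

    abundance: np.ndarray
    fluorophore: str
    marker: str
    origin: tuple[int, int] = (0, 0)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=np.float32)
        if self.abundance.ndim != 2:
            raise ValueError("abundance plane must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.abundance.shape


def _nnls_pixels(S: np.ndarray, pixels: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Non-negative least squares for many pixels against library matrix S.

    S has shape (B, F); pixels has shape (N, B).  The unconstrained solution
    is computed for all pixels in one solve; only pixels whose solution
    violates non-negativity beyond a small numerical tolerance fall back to
    the active-set NNLS routine.
    """
    coef, *_ = np.linalg.lstsq(S, pixels.T, rcond=None)
    coef = coef.T  # (N, F)
    scale = np.maximum(np.abs(pixels).max(axis=1), 1.0)
    bad = (coef < -tol * scale[:, None]).any(axis=1)
    coef[coef < 0] = 0.0
    if np.any(bad):
        for i in np.flatnonzero(bad):
            coef[i], _ = scipy.optimize.nnls(S, pixels[i])
    return coef


def unmix_tile(tile: MultispectralTile, library: SpectralLibrary) -> list[ChannelPlane]:
    """Decompose a multispectral tile into one abundance plane per fluorophore.

    Per pixel, abundances minimize the squared reconstruction error against
    the library spectra subject to non-negativity.

    Raises
    ------
    ConfigurationError
        if the library has fewer bands than fluorophores (underdetermined).
    ValueError
        if the tile band count does not match the library band axis.
    """
    H, W, B = tile.intensities.shape
    if B != library.n_bands:
        raise ValueError(f"tile has {B} bands but library has {library.n_bands}")
    F = len(library.fluorophores)
    if B < F:
        raise ConfigurationError(f"{B} bands cannot resolve {F} fluorophores")
    S = library.spectra.T  # (B, F)
    pixels = tile.intensities.reshape(-1, B)
    coef = _nnls_pixels(S, pixels)
    planes = []
    for i, fluor in enumerate(library.fluorophores):
        planes.append(
            ChannelPlane(
                abundance=coef[:, i].reshape(H, W),
                fluorophore=fluor,
                marker=library.marker_for(fluor),
                origin=tile.origin,
                pixel_size=tile.pixel_size,
            )
        )
    return planes


def stitch_planes(planes: list[ChannelPlane], canvas_size: tuple[int, int]) -> ChannelPlane:
    """Stitch single-fluorophore tile planes into one plane by stored origins.

    Parameters
    ----------
    planes
        Planes sharing one fluorophore and pixel size.
    canvas_size
        (width, height) of the output plane in pixels; must contain all tiles.

    Pixels covered by no tile are 0.  Overlapping tiles are resolved
    last-written-wins with a logged warning (the acquisition produces
    non-overlapping tiles, so overlap indicates a configuration problem).
    """
    if not planes:
        raise ValueError("no planes to stitch")
    fluor = planes[0].fluorophore
    px = planes[0].pixel_size
    for p in planes:
        if p.fluorophore != fluor:
            raise ValueError(f"mixed fluorophores: {p.fluorophore} vs {fluor}")
        if p.pixel_size != px:
            raise ValueError("mixed pixel sizes")
    W, H = canvas_size
    canvas = np.zeros((H, W), dtype=np.float32)
    covered = np.zeros((H, W), dtype=bool)
    overlap_warned = False
    for p in planes:
        x0, y0 = p.origin
        h, w = p.abundance.shape
        if x0 + w > W or y0 + h > H:
            raise ValueError(f"tile at {p.origin} with shape {(h, w)} exceeds canvas {canvas_size}")
        region = covered[y0:y0 + h, x0:x0 + w]
        if region.any() and not overlap_warned:
            logger.warning("overlapping tiles at origin %s; last written wins", p.origin)
            overlap_warned = True
        canvas[y0:y0 + h, x0:x0 + w] = p.abundance
        region[:] = True
    return ChannelPlane(canvas, fluor, planes[0].marker, origin=(0, 0), pixel_size=px)
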