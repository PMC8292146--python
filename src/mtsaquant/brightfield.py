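"""Artificial brightfield IHC synthesis from unmixed fluorescence planes.

A DAPI plane (nuclear counterstain) and one marker plane are recoloured as a
virtual hematoxylin/DAB slide through the Beer-Lambert law: for each RGB
channel ch,

    out_ch = 255 * exp(-(I_dapi * c_ch,Hem + I_ihc * c_ch,DAB))

where I_dapi, I_ihc are intensities normalized to [0, 1] and c_ch,st is the
light absorption of dye st in that part of the spectrum.  Zero signal maps to
white (255, 255, 255); increasing signal darkens each channel monotonically.
The resulting images can be fed to cell detectors developed for conventional
chromogenic IHC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mtsaquant.unmix import ChannelPlane, ConfigurationError


@dataclass(frozen=True)
class StainVector:
    """Light-absorption coefficients of a dye in the R, G and B channels."""

    dye: str
    c_r: float
    c_g: float
    c_b: float

    def __post_init__(self) -> None:
        c = (self.c_r, self.c_g, self.c_b)
        if any(v < 0 for v in c):
            raise ValueError("absorption coefficients must be non-negative")
        if all(v == 0 for v in c):
            raise ValueError("stain vector must not be all-zero")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.c_r, self.c_g, self.c_b], dtype=np.float64)


# Ruifrok-Johnston colour-deconvolution optical-density triplets, the standard
# published hematoxylin and DAB absorption signatures.
HEMATOXYLIN = StainVector("hematoxylin", 0.650, 0.704, 0.286)
DAB = StainVector("DAB", 0.269, 0.568, 0.777)


@dataclass
class BrightfieldImage:
    """8-bit RGB artificial brightfield image with its provenance."""

    rgb: np.ndarray  # H x W x 3, uint8
    marker: str
    hematoxylin: StainVector
    dab: StainVector
    scale_max: float
    pixel_size: float
    rgb_float: np.ndarray | None = None  # pre-quantization image, H x W x 3 in [0, 255]


def normalize_intensity(plane: ChannelPlane, scale_max: float | None = None) -> ChannelPlane:
    """Scale a plane into [0, 1], clipping values above ``scale_max``.

    ``scale_max=None`` uses the plane's 99.9th percentile (robust to hot
    pixels); a fixed constant makes runs comparable across slides.
    """
    if scale_max is not None and scale_max <= 0:
        raise ValueError(f"scale_max must be positive, got {scale_max}")
    data = plane.abundance.astype(np.float64)
    if scale_max is None:
        scale_max = float(np.percentile(data, 99.9))
        if scale_max <= 0:
            scale_max = 1.0
    out = np.clip(data / scale_max, 0.0, 1.0)
    return ChannelPlane(out, plane.fluorophore, plane.marker, plane.origin, plane.pixel_size)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; 8-bit quantization here rounds half away from zero
    return np.floor(x + 0.5)


def convert_to_brightfield(
    i_dapi: ChannelPlane,
    i_ihc: ChannelPlane,
    hem: StainVector = HEMATOXYLIN,
    dab: StainVector = DAB,
    scale_max: float = 1.0,
    keep_float: bool = False,
) -> BrightfieldImage:
    """Render normalized DAPI + marker planes as an artificial H/DAB image.

    Both planes must share geometry and hold values in [0, 1].  All math is
    floating point; quantization to 8 bits happens once at the end.  With
    ``keep_float=True`` the pre-quantization float image is retained, which
    allows exact optical-density inversion (see :func:`invert_brightfield`).
    """
    if i_dapi.shape != i_ihc.shape:
        raise ValueError(f"plane geometry mismatch: {i_dapi.shape} vs {i_ihc.shape}")
    d = i_dapi.abundance.astype(np.float64)
    m = i_ihc.abundance.astype(np.float64)
    od = d[..., None] * hem.as_array + m[..., None] * dab.as_array  # H x W x 3
    rgb_float = 255.0 * np.exp(-od)
    rgb = _round_half_away(rgb_float).astype(np.uint8)
    return BrightfieldImage(
        rgb=rgb,
        marker=i_ihc.marker,
        hematoxylin=hem,
        dab=dab,
        scale_max=scale_max,
        pixel_size=i_ihc.pixel_size,
        rgb_float=rgb_float if keep_float else None,
    )


def invert_brightfield(
    rgb: np.ndarray,
    hem: StainVector = HEMATOXYLIN,
    dab: StainVector = DAB,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover (I_dapi, I_ihc) from a brightfield image by colour deconvolution.

    Converts RGB back to optical densities OD_ch = -ln(out_ch / 255) and
    solves the overdetermined 3x2 linear system per pixel by least squares.
    Requires linearly independent stain vectors.  On the pre-quantization
    float image the recovery is exact to numerical precision; on the 8-bit
    image it carries quantization noise.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    od = -np.log(np.maximum(rgb, 1e-8) / 255.0)  # H x W x 3
    M = np.stack([hem.as_array, dab.as_array], axis=1)  # 3 x 2
    if np.linalg.matrix_rank(M) < 2:
        raise ConfigurationError("stain vectors are linearly dependent")
    sol, *_ = np.linalg.lstsq(M, od.reshape(-1, 3).T, rcond=None)
    i_dapi = sol[0].reshape(od.shape[:2])
    i_ihc = sol[1].reshape(od.shape[:2])
    return i_dapi, i_ihc


def assemble_pairs(
    stack: dict[str, ChannelPlane],
    dapi_label: str = "DAPI",
    hem: StainVector = HEMATOXYLIN,
    dab: StainVector = DAB,
    scale_max: float | None = None,
    keep_float: bool = False,
) -> list[tuple[str, BrightfieldImage]]:
    """Pair the shared DAPI plane with each marker plane and convert each pair.

    Returns one (marker, image) per non-DAPI marker in stack order.  Planes
    are normalized with :func:`normalize_intensity` before conversion.
    """
    if dapi_label not in stack:
        raise ConfigurationError(f"stack has no {dapi_label!r} plane")
    dapi_n = normalize_intensity(stack[dapi_label], scale_max)
    out: list[tuple[str, BrightfieldImage]] = []
    for marker, plane in stack.items():
        if marker == dapi_label:
            continue
        img = convert_to_brightfield(
            dapi_n, normalize_intensity(plane, scale_max), hem, dab,
            scale_max=scale_max or 1.0, keep_float=keep_float,
        )
        out.append((marker, img))
    return out
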