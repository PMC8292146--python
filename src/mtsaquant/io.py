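"""File I/O: multi-channel TIFF tiles/planes with origin metadata, detection CSV.

Tiles and planes travel as TIFF with a JSON ImageDescription carrying the
global origin, pixel size and channel labels, so stitching can run from files
alone.  Detections travel as CSV with both pixel and micrometre coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from mtsaquant.detect import Detection
from mtsaquant.unmix import ChannelPlane, MultispectralTile

DETECTION_COLUMNS = ["marker", "x_px", "y_px", "x_um", "y_um", "confidence"]


def write_tile(path, tile: MultispectralTile) -> None:
    meta = {"origin": list(tile.origin), "pixel_size": tile.pixel_size, "kind": "multispectral"}
    data = np.moveaxis(tile.intensities.astype(np.float32), -1, 0)  # bands first
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_tile(path) -> MultispectralTile:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return MultispectralTile(
        intensities=np.moveaxis(data, 0, -1),
        origin=tuple(meta["origin"]),
        pixel_size=meta["pixel_size"],
    )


def write_plane(path, plane: ChannelPlane) -> None:
    meta = {
        "origin": list(plane.origin), "pixel_size": plane.pixel_size,
        "fluorophore": plane.fluorophore, "marker": plane.marker, "kind": "channel_plane",
    }
    tifffile.imwrite(str(path), plane.abundance.astype(np.float32), description=json.dumps(meta))


def read_plane(path) -> ChannelPlane:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return ChannelPlane(
        abundance=data,
        fluorophore=meta["fluorophore"],
        marker=meta["marker"],
        origin=tuple(meta["origin"]),
        pixel_size=meta["pixel_size"],
    )


def write_rgb_tiff(path, rgb: np.ndarray, pixel_size: float, tile: int = 256) -> None:
    """Tiled RGB TIFF with a two-level pyramid so WSI viewers can open it."""
    h, w = rgb.shape[:2]
    options = dict(tile=(tile, tile), photometric="rgb")
    with tifffile.TiffWriter(str(path)) as tw:
        tw.write(rgb, subifds=1, resolution=(1e4 / pixel_size, 1e4 / pixel_size),
                 resolutionunit="CENTIMETER", **options)
        tw.write(rgb[::2, ::2], subfiletype=1, **options)


def write_detections_csv(path, detections, pixel_size: float) -> None:
    rows = [
        {"marker": d.marker, "x_px": d.x, "y_px": d.y,
         "x_um": d.x * pixel_size, "y_um": d.y * pixel_size, "confidence": d.confidence}
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(x=float(r.x_px), y=float(r.y_px),
                  confidence=float(r.confidence), marker=str(r.marker))
        for r in df.itertuples()
    ]


def glob_planes(directory, pattern: str = "*.tif*") -> list[ChannelPlane]:
    return [read_plane(p) for p in sorted(Path(directory).glob(pattern))]
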