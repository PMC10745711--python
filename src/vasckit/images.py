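"""Calibrated raster containers shared by every imaging assay.

All spatial quantities carried by these containers are physical
(micrometres, seconds); pixel indices never leak into downstream APIs.
Coordinates follow the pixel-center convention with the origin at the
top-left pixel, x increasing rightward (columns) and y downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class RasterImage:
    """A single 2D intensity (or binary) image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (ny, nx)
        Intensity grid in arbitrary units, or a boolean mask.
    pixel_size : float
        Edge length of a pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (μm/pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size**2

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) of the field in μm."""
        ny, nx = self.pixels.shape
        return nx * self.pixel_size, ny * self.pixel_size

    def as_bool(self) -> np.ndarray:
        """Binary view; raises if the image is not two-valued."""
        if self.pixels.dtype == bool:
            return self.pixels
        vals = np.unique(self.pixels)
        if vals.size > 2:
            raise ValueError("image is not binary")
        return self.pixels > vals.min()

    def save_tiff(self, path: str | Path) -> None:
        _write_tiff(path, np.asarray(self.pixels, dtype=np.float32)[None],
                    self.pixel_size, frame_interval=None)


@dataclass
class ImageStack:
    """A time-lapse stack: frames share a grid and carry timestamps.

    ``times`` are seconds from the start of acquisition and must be
    strictly increasing.
    """

    frames: np.ndarray  # (nt, ny, nx)
    pixel_size: float
    times: np.ndarray  # (nt,), seconds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (time, y, x)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (μm/pixel)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> RasterImage:
        return RasterImage(self.frames[i], self.pixel_size)

    def save_tiff(self, path: str | Path) -> None:
        dt = float(np.median(np.diff(self.times))) if self.n_frames > 1 else None
        _write_tiff(path, np.asarray(self.frames, dtype=np.float32),
                    self.pixel_size, frame_interval=dt)


def _write_tiff(path, data, pixel_size, frame_interval):
    # ImageJ-style metadata keeps pixel size and frame interval readable
    # by Fiji as well as by load_stack below.
    meta = {"unit": "um", "spacing": 1.0}
    if frame_interval is not None:
        meta["finterval"] = frame_interval
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata=meta,
    )


def load_image(path: str | Path, pixel_size: float | None = None) -> RasterImage:
    """Read a single-frame TIFF; pixel size from tags unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        px = pixel_size if pixel_size is not None else _pixel_size_from_tags(tf)
    data = np.squeeze(data)
    if data.ndim == 3:
        data = data[0]
    return RasterImage(data, px)


def load_stack(path: str | Path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read a multi-frame TIFF stack written by :meth:`ImageStack.save_tiff`."""
    with tifffile.TiffFile(path) as tf:
        data = np.asarray(tf.asarray())
        px = pixel_size if pixel_size is not None else _pixel_size_from_tags(tf)
        if frame_interval is None:
            ij = tf.imagej_metadata or {}
            frame_interval = ij.get("finterval", 1.0)
    if data.ndim == 2:
        data = data[None]
    data = data.reshape(-1, *data.shape[-2:])
    times = np.arange(data.shape[0]) * float(frame_interval)
    if data.shape[0] == 1:
        times = np.array([0.0])
    return ImageStack(data, px, times)


def _pixel_size_from_tags(tf: tifffile.TiffFile) -> float:
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        res = xres[0] / xres[1]
        if res > 0:
            return 1.0 / res
    except (KeyError, ZeroDivisionError):
        pass
    raise ValueError("no pixel size in TIFF tags; pass pixel_size explicitly")
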