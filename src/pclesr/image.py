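"""Cartesian image container with FoV mask and provenance, plus file I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidArgumentError

__all__ = ["CartesianImage", "save_image", "load_image"]


@dataclass
class CartesianImage:
    """2-D intensity grid with an attached FoV validity mask.

    ``pixels`` is a ``(rows, cols)`` float array in linear intensity units;
    ``fov_mask`` a boolean array of the same shape (pixels outside the
    bundle's circular field of view carry no signal); ``meta`` records
    provenance (source image, lattice, noise parameters, processing steps).
    """

    pixels: np.ndarray
    fov_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise InvalidArgumentError("pixels must be a 2-D array")
        if self.fov_mask.shape != self.pixels.shape:
            raise InvalidArgumentError("fov_mask shape must match pixels shape")
        if not np.all(np.isfinite(self.pixels[self.fov_mask])):
            raise InvalidArgumentError("in-FoV pixels must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def in_fov(self) -> np.ndarray:
        """1-D array of the in-FoV pixel values."""
        return self.pixels[self.fov_mask]

    def with_pixels(self, pixels: np.ndarray, extra_meta: dict | None = None) -> "CartesianImage":
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return CartesianImage(pixels=pixels, fov_mask=self.fov_mask.copy(), meta=meta)


def save_image(image: CartesianImage, path: str | Path) -> None:
    """Write a 32-bit float TIFF (or 16-bit PNG) plus mask and JSON sidecar.

    ``<stem>.tiff`` holds the intensities, ``<stem>_mask.png`` the FoV mask,
    ``<stem>.json`` the provenance metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    elif path.suffix.lower() == ".png":
        arr = np.clip(image.pixels, 0.0, 1.0)
        iio.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))
    else:
        raise InvalidArgumentError(f"unsupported image format: {path.suffix}")
    iio.imwrite(path.with_name(path.stem + "_mask.png"), image.fov_mask.astype(np.uint8) * 255)
    path.with_suffix(".json").write_text(json.dumps(image.meta, default=str))


def load_image(path: str | Path) -> CartesianImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path).astype(np.float64)
    elif path.suffix.lower() == ".png":
        pixels = iio.imread(path).astype(np.float64) / 65535.0
    else:
        raise InvalidArgumentError(f"unsupported image format: {path.suffix}")
    mask_path = path.with_name(path.stem + "_mask.png")
    if mask_path.exists():
        mask = iio.imread(mask_path) > 0
    else:
        mask = np.ones_like(pixels, dtype=bool)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CartesianImage(pixels=pixels, fov_mask=mask, meta=meta)
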