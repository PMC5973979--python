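"""Synthetic high-resolution phantoms.

Real training targets in this domain are video-registration-derived
pseudo-HR endomicroscopy frames: high-SNR images of epithelial tissue with
fine cellular detail inside a circular field of view.  The phantoms
emulate their statistics with randomly placed anisotropic Gaussian blobs
(cell- and crypt-like structures, bright and dark) over a smooth
low-frequency background, normalised to [0, 1] inside the FoV and zero
outside.  Two texture presets with distinct parameter ranges stand in for
the two tissue types (colon-like round crypts vs oesophagus-like
elongated cells) so that stratified splitting can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .image import CartesianImage

__all__ = ["TextureParams", "STRATA_PRESETS", "generate_phantom_hr"]


@dataclass(frozen=True)
class TextureParams:
    """Parameter ranges for the blob phantom (all lengths in pixels)."""

    base_level: float = 0.35
    background_amp: float = 0.12
    background_scale: float = 0.35  # fraction of the FoV radius
    blob_sigma_range: tuple[float, float] = (2.5, 6.0)
    blob_aspect_range: tuple[float, float] = (1.0, 2.5)
    blob_amp_range: tuple[float, float] = (0.25, 0.9)
    dark_fraction: float = 0.25  # fraction of blobs with negative amplitude


#: Texture presets emulating the two tissue strata of a colon/oesophagus
#: endomicroscopy collection.
STRATA_PRESETS: dict[str, TextureParams] = {
    # round, larger crypt-like structures
    "colon": TextureParams(blob_sigma_range=(3.5, 7.0), blob_aspect_range=(1.0, 1.6)),
    # smaller, elongated cell-border-like structures
    "oesophagus": TextureParams(blob_sigma_range=(2.0, 4.5), blob_aspect_range=(1.8, 3.5)),
}


def generate_phantom_hr(
    grid_shape: tuple[int, int],
    fov_center: tuple[float, float],
    fov_radius: float,
    n_blobs: int = 150,
    texture_params: TextureParams | None = None,
    seed: int = 0,
) -> CartesianImage:
    """Render a blob phantom inside a circular FoV; deterministic per seed.

    The result is min-max normalised to [0, 1] over in-FoV pixels (a
    constant frame, e.g. ``n_blobs=0`` with zero background amplitude, is
    left at its base level) and zeroed outside the FoV.
    """
    if n_blobs < 0:
        raise InvalidArgumentError("n_blobs must be >= 0")
    tp = texture_params or TextureParams()
    rows, cols = grid_shape
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    r0, c0 = fov_center
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= fov_radius**2

    img = np.full(grid_shape, tp.base_level)
    if tp.background_amp > 0:
        # a handful of broad Gaussians gives a smooth low-frequency field
        scale = tp.background_scale * fov_radius
        for _ in range(4):
            br = r0 + rng.uniform(-0.8, 0.8) * fov_radius
            bc = c0 + rng.uniform(-0.8, 0.8) * fov_radius
            amp = rng.uniform(-1.0, 1.0) * tp.background_amp
            img += amp * np.exp(-(((rr - br) ** 2 + (cc - bc) ** 2) / (2.0 * scale**2)))

    for _ in range(n_blobs):
        # uniform centre in the FoV disc
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rad = fov_radius * 0.97 * np.sqrt(rng.uniform(0.0, 1.0))
        br, bc = r0 + rad * np.sin(theta), c0 + rad * np.cos(theta)
        s_minor = rng.uniform(*tp.blob_sigma_range)
        s_major = s_minor * rng.uniform(*tp.blob_aspect_range)
        phi = rng.uniform(0.0, np.pi)
        amp = rng.uniform(*tp.blob_amp_range)
        if rng.uniform() < tp.dark_fraction:
            amp = -amp
        # render on a local window (4 sigma) for speed
        ext = int(np.ceil(4.0 * s_major))
        rlo, rhi = max(0, int(br) - ext), min(rows, int(br) + ext + 1)
        clo, chi = max(0, int(bc) - ext), min(cols, int(bc) + ext + 1)
        if rlo >= rhi or clo >= chi:
            continue
        wr = rr[rlo:rhi, clo:chi] - br
        wc = cc[rlo:rhi, clo:chi] - bc
        u = wr * np.cos(phi) + wc * np.sin(phi)
        v = -wr * np.sin(phi) + wc * np.cos(phi)
        img[rlo:rhi, clo:chi] += amp * np.exp(
            -(u**2 / (2.0 * s_major**2) + v**2 / (2.0 * s_minor**2))
        )

    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    img[~mask] = 0.0
    return CartesianImage(
        pixels=img,
        fov_mask=mask,
        meta={"source_id": f"phantom-seed{seed}", "n_blobs": n_blobs},
    )


def stratum_params(stratum: str) -> TextureParams:
    """Texture preset for a stratum label."""
    try:
        return STRATA_PRESETS[stratum]
    except KeyError as exc:
        raise InvalidArgumentError(f"unknown stratum {stratum!r}") from exc
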