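"""Forward model: from a high-resolution image to noisy per-fibre signals.

Each fibre of the bundle acts as a single-pixel detector.  Its clean
signal is pooled from the HR image either by averaging over the fibre's
Voronoi cell or by averaging the ``k`` nearest pixels (the acquisition
variant of the standard reconstruction algorithm, ``k=7`` by default).
Realistic corruption applies multiplicative and additive Gaussian noise:

    nfs = (1 + m) * fs + a,

with ``m ~ N(0, sigma_m^2)`` and ``a ~ N(0, (sigma_a_coeff * range(fs))^2)``
drawn independently per fibre.  Defaults ``sigma_m = 0.05`` and
``sigma_a_coeff = 0.01`` reproduce the noise level of real bundle
acquisitions.  No clipping is applied: downstream per-frame
standardisation makes the absolute range irrelevant, and clipping would
distort the Gaussian model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, InvalidStateError
from .image import CartesianImage
from .lattice import FibreLattice, PixelAssignment

__all__ = [
    "FibreSignals",
    "NoiseParams",
    "extract_fibre_signals",
    "extract_fibre_signals_neighbourhood",
    "apply_noise",
    "save_signals",
    "load_signals",
]


@dataclass(frozen=True)
class FibreSignals:
    """Per-fibre scalar intensities, index-aligned with a lattice."""

    values: np.ndarray
    lattice_ref: str = ""
    noisy: bool = False

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1:
            raise InvalidArgumentError("values must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise InvalidArgumentError("fibre signals must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n_fibres(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the multiplicative/additive Gaussian noise model."""

    sigma_m: float = 0.05
    sigma_a_coeff: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.sigma_m < 0 or self.sigma_a_coeff < 0:
            raise InvalidArgumentError("noise standard deviations must be non-negative")


def extract_fibre_signals(hr: CartesianImage, assignment: PixelAssignment) -> FibreSignals:
    """Pool the HR image into per-fibre signals by Voronoi-cell averaging.

    ``value[i]`` is the arithmetic mean of the in-FoV pixels assigned to
    fibre ``i``.  A fibre whose Voronoi cell contains no in-FoV pixel
    (possible at desk-scale fibre densities) receives the image value at
    the pixel nearest its position.
    """
    if hr.grid_shape != assignment.grid_shape:
        raise InvalidArgumentError(
            f"image shape {hr.grid_shape} != assignment shape {assignment.grid_shape}"
        )
    amap = assignment.fibre_index_per_pixel
    inside = amap >= 0
    idx = amap[inside]
    n = assignment.n_fibres
    sums = np.bincount(idx, weights=hr.pixels[inside], minlength=n)
    counts = np.bincount(idx, minlength=n)
    values = np.zeros(n)
    occupied = counts > 0
    values[occupied] = sums[occupied] / counts[occupied]
    return FibreSignals(values=values, lattice_ref=str(hr.meta.get("lattice_id", "")), noisy=False)


def fill_empty_cells(
    values: np.ndarray, counts: np.ndarray, lattice: FibreLattice, pixels: np.ndarray
) -> np.ndarray:
    """Assign fibres with empty Voronoi cells the value of their nearest pixel."""
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        rows = np.clip(np.rint(lattice.positions[empty, 0]).astype(int), 0, pixels.shape[0] - 1)
        cols = np.clip(np.rint(lattice.positions[empty, 1]).astype(int), 0, pixels.shape[1] - 1)
        values = values.copy()
        values[empty] = pixels[rows, cols]
    return values


def extract_fibre_signals_voronoi(
    hr: CartesianImage, assignment: PixelAssignment, lattice: FibreLattice
) -> FibreSignals:
    """Voronoi-cell averaging with nearest-pixel fallback for empty cells."""
    fs = extract_fibre_signals(hr, assignment)
    amap = assignment.fibre_index_per_pixel
    counts = np.bincount(amap[amap >= 0], minlength=assignment.n_fibres)
    values = fill_empty_cells(fs.values, counts, lattice, hr.pixels)
    return FibreSignals(values=values, lattice_ref=fs.lattice_ref, noisy=False)


def extract_fibre_signals_neighbourhood(
    image: CartesianImage, lattice: FibreLattice, k: int = 7
) -> FibreSignals:
    """Average the ``k`` in-FoV pixels nearest each fibre position.

    Mimics the acquisition step of the standard bundle reconstruction,
    which pools seven neighbouring pixels per fibre.  Distance ties at
    the ``k``-th neighbour are resolved towards the lower row-major
    pixel index.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    pix_coords = np.argwhere(image.fov_mask).astype(float)
    if k > pix_coords.shape[0]:
        raise InvalidArgumentError(
            f"k={k} exceeds the in-FoV pixel count {pix_coords.shape[0]}"
        )
    pix_values = image.pixels[image.fov_mask]
    tree = cKDTree(pix_coords)
    kq = min(k + 8, pix_coords.shape[0])
    d, idx = tree.query(lattice.positions, k=kq)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    values = np.empty(lattice.n_fibres)
    tol = 1e-9
    for i in range(lattice.n_fibres):
        dk = d[i, k - 1]
        if kq > k and d[i, k] <= dk + tol:
            sure = idx[i, d[i] < dk - tol]
            tied = np.sort(idx[i, np.abs(d[i] - dk) <= tol])
            chosen = np.concatenate([sure, tied[: k - sure.size]])
        else:
            chosen = idx[i, :k]
        values[i] = pix_values[chosen].mean()
    return FibreSignals(values=values, lattice_ref=str(image.meta.get("lattice_id", "")), noisy=False)


def apply_noise(fs: FibreSignals, params: NoiseParams) -> FibreSignals:
    """Corrupt clean fibre signals with the multiplicative/additive model.

    The additive standard deviation scales with the clean-signal range of
    this frame, ``sigma_a_coeff * (max fs - min fs)``, so a flat frame
    receives no additive noise.  Deterministic per ``params.seed``.
    """
    if fs.noisy:
        raise InvalidStateError("signals are already noisy; refusing double corruption")
    rng = np.random.default_rng(params.seed)
    n = fs.n_fibres
    m = rng.normal(0.0, params.sigma_m, size=n) if params.sigma_m > 0 else np.zeros(n)
    signal_range = float(fs.values.max() - fs.values.min())
    sigma_a = params.sigma_a_coeff * signal_range
    a = rng.normal(0.0, sigma_a, size=n) if sigma_a > 0 else np.zeros(n)
    nfs = (1.0 + m) * fs.values + a
    return FibreSignals(values=nfs, lattice_ref=fs.lattice_ref, noisy=True)


def estimate_noise_params(clean: np.ndarray, noisy: np.ndarray, n_iter: int = 3) -> tuple[float, float]:
    """Moment-based recovery of the noise parameters from clean/noisy pairs.

    Under the forward model, ``E[(nfs - fs)^2 | fs] = sigma_m^2 fs^2 +
    sigma_a^2``, so regressing the squared perturbation on the squared
    clean signal identifies both parameters: the slope is ``sigma_m^2``
    and the intercept ``sigma_a^2``.  The squared perturbations are
    strongly heteroscedastic (variance ``2 (sigma_m^2 fs^2 + sigma_a^2)^2``),
    so an iterated variance-weighted fit is used.  Returns
    ``(sigma_m_hat, sigma_a_coeff_hat)`` with the additive part expressed
    as a coefficient of the clean-signal range.
    """
    clean = np.asarray(clean, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    if clean.shape != noisy.shape or clean.ndim != 1 or clean.size < 3:
        raise InvalidArgumentError("clean/noisy must be equal-length 1-D arrays, n >= 3")
    x = clean**2
    y = (noisy - clean) ** 2
    X = np.stack([x, np.ones_like(x)], axis=1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(n_iter):
        w = 1.0 / np.maximum(X @ beta, 1e-12)
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)
    slope, intercept = beta
    signal_range = float(clean.max() - clean.min())
    if signal_range <= 0:
        raise InvalidArgumentError("clean signals must span a nonzero range")
    sigma_m = float(np.sqrt(max(slope, 0.0)))
    sigma_a_coeff = float(np.sqrt(max(intercept, 0.0)) / signal_range)
    return sigma_m, sigma_a_coeff


def save_signals(fs: FibreSignals, path: str | Path) -> None:
    """CSV with a one-line JSON comment header carrying lattice_ref/noisy."""
    import json

    df = pd.DataFrame({"fibre_index": np.arange(fs.n_fibres), "value": fs.values})
    header = "# " + json.dumps({"lattice_ref": fs.lattice_ref, "noisy": fs.noisy}) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_signals(path: str | Path) -> FibreSignals:
    import json

    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    fields = json.loads(header.lstrip("# ")) if header.startswith("#") else {}
    return FibreSignals(
        values=df["value"].to_numpy(),
        lattice_ref=fields.get("lattice_ref", ""),
        noisy=bool(fields.get("noisy", False)),
    )
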