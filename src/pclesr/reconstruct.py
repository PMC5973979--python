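"""Bundle-image reconstruction and the end-to-end LR synthesis pipeline.

Scattered fibre signals are mapped back to a Cartesian grid by
piecewise-linear (barycentric) interpolation over the Delaunay
triangulation of the fibre positions — the same scheme the clinical
reconstruction software uses.  ``simulate_lr`` composes the full forward
pipeline: Voronoi signal extraction, noise corruption, and interpolation,
yielding a low-resolution frame perfectly aligned with its HR source.
"LR" here means fibre-limited resolution on the *same* pixel grid as the
HR input; the loss of resolution comes from the fibre sampling, not from
pixel decimation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError
from .image import CartesianImage
from .lattice import FibreLattice, Triangulation, fov_mask, nearest_fibre_map, triangulate
from .signals import (
    FibreSignals,
    NoiseParams,
    apply_noise,
    extract_fibre_signals_voronoi,
)

__all__ = ["interpolate_linear", "simulate_lr"]


def interpolate_linear(
    fs: FibreSignals,
    tri: Triangulation,
    lattice: FibreLattice,
    grid_shape: tuple[int, int],
) -> CartesianImage:
    """Piecewise-linear interpolation of fibre signals onto a pixel grid.

    In-FoV pixels inside the convex hull of the fibre positions get the
    barycentric combination of their enclosing triangle's three fibre
    values; in-FoV pixels outside the hull (the FoV rim) get the nearest
    fibre's value, so the reconstruction is defined over the whole FoV.
    Out-of-FoV pixels are zero with a false mask.
    """
    if fs.n_fibres != lattice.n_fibres:
        raise InvalidArgumentError("signals are not aligned with the lattice")
    if tri.lattice is not lattice and not np.array_equal(tri.lattice.positions, lattice.positions):
        raise InvalidArgumentError("triangulation was not built from this lattice")
    mask = fov_mask(lattice, grid_shape)
    pixels = np.zeros(grid_shape)
    pts = np.argwhere(mask).astype(float)
    if pts.size == 0:
        return CartesianImage(pixels=pixels, fov_mask=mask)
    simplex = tri.find_simplex(pts)
    inside = simplex >= 0
    values = np.empty(pts.shape[0])
    if np.any(inside):
        bary = tri.barycentric(pts[inside], simplex[inside])
        verts = tri.simplices[simplex[inside]]
        values[inside] = np.einsum("mi,mi->m", bary, fs.values[verts])
    if np.any(~inside):
        tree = cKDTree(lattice.positions)
        _, nearest = tree.query(pts[~inside])
        values[~inside] = fs.values[nearest]
    pixels[mask] = values
    return CartesianImage(pixels=pixels, fov_mask=mask)


def simulate_lr(
    hr: CartesianImage,
    lattice: FibreLattice,
    params: NoiseParams,
    tri: Triangulation | None = None,
) -> CartesianImage:
    """Run the full HR → LR forward pipeline on one frame.

    Composition of Voronoi signal extraction, multiplicative/additive
    noise, and Delaunay piecewise-linear interpolation.  The output frame
    shares the HR pixel grid and carries full provenance in ``meta``.
    A pre-built triangulation may be passed to amortise geometry cost
    over many frames of the same lattice.
    """
    assignment = nearest_fibre_map(lattice, hr.grid_shape)
    fs = extract_fibre_signals_voronoi(hr, assignment, lattice)
    nfs = apply_noise(fs, params)
    if tri is None:
        tri = triangulate(lattice)
    lr = interpolate_linear(nfs, tri, lattice, hr.grid_shape)
    lr.meta.update(
        {
            "source_id": hr.meta.get("source_id", ""),
            "lattice_id": f"hex-jitter-n{lattice.n_fibres}-seed{lattice.seed}",
            "noise_params": {
                "sigma_m": params.sigma_m,
                "sigma_a_coeff": params.sigma_a_coeff,
                "seed": params.seed,
            },
            "history": ["voronoi_extract", "noise", "delaunay_linear_interp", "rim_nearest_fill"],
        }
    )
    return lr
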