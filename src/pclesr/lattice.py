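"""Fibre-bundle lattice geometry.

A coherent fibre bundle samples the tissue on an irregular, roughly
hexagonal grid of a few tens of thousands of fibre cores confined to a
circular field of view (FoV).  This module synthesises statistically
similar lattices (perturbed hexagonal packing), partitions a pixel grid
into per-fibre Voronoi cells, triangulates the fibre positions for
piecewise-linear reconstruction, and builds the FoV validity mask.

Coordinate convention: pixel centers sit at integer coordinates,
``(row, col)`` order, 0-based.  All positions and radii are in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "FibreLattice",
    "PixelAssignment",
    "Triangulation",
    "generate_fibre_lattice",
    "nearest_fibre_map",
    "triangulate",
    "fov_mask",
    "save_lattice",
    "load_lattice",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class FibreLattice:
    """Irregular fibre positions inside a circular field of view.

    Parameters
    ----------
    positions
        ``(n_fibres, 2)`` float array of fibre core centres, ``(row, col)``.
    fov_center
        ``(row, col)`` centre of the circular FoV.
    fov_radius
        FoV radius in pixels.
    seed
        Seed used by the generator, or ``None`` for externally supplied
        lattices.
    """

    positions: np.ndarray
    fov_center: tuple[float, float]
    fov_radius: float
    seed: int | None = None
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 3:
            raise InvalidArgumentError("positions must be (n>=3, 2)")
        object.__setattr__(self, "positions", pos)
        r = np.hypot(pos[:, 0] - self.fov_center[0], pos[:, 1] - self.fov_center[1])
        if np.any(r > self.fov_radius + 1e-9):
            raise InvalidArgumentError("all fibre positions must lie inside the FoV disc")

    @property
    def n_fibres(self) -> int:
        return self.positions.shape[0]

    @property
    def pitch(self) -> float:
        """Median nearest-neighbour spacing (pixels)."""
        tree = cKDTree(self.positions)
        d, _ = tree.query(self.positions, k=2)
        return float(np.median(d[:, 1]))


@dataclass(frozen=True)
class PixelAssignment:
    """Voronoi partition of a pixel grid: nearest fibre per pixel.

    ``fibre_index_per_pixel`` is an integer map of shape ``grid_shape``;
    out-of-FoV pixels carry ``-1``.
    """

    grid_shape: tuple[int, int]
    fibre_index_per_pixel: np.ndarray
    n_fibres: int

    def pixels_of(self, fibre: int) -> np.ndarray:
        """(k, 2) array of (row, col) pixel coordinates assigned to ``fibre``."""
        return np.argwhere(self.fibre_index_per_pixel == fibre)


class Triangulation:
    """Delaunay triangulation of the fibre positions.

    Thin wrapper over :class:`scipy.spatial.Delaunay` pinning the input
    by a deterministic sub-float perturbation so that co-circular fibre
    configurations triangulate reproducibly.
    """

    def __init__(self, lattice: FibreLattice):
        pos = lattice.positions
        if pos.shape[0] < 3:
            raise InvalidArgumentError("triangulation needs at least 3 fibres")
        centered = pos - pos.mean(axis=0)
        # rank < 2 <=> all fibres collinear
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
            raise DegenerateGeometryError("all fibre positions are collinear")
        eps = 1e-9 * lattice.pitch
        idx = np.arange(pos.shape[0], dtype=float)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        perturbed = pos + eps * np.stack([np.cos(golden * idx), np.sin(golden * idx)], axis=1)
        try:
            self._dt = Delaunay(perturbed)
        except QhullError as exc:  # pragma: no cover - rank check catches most
            raise DegenerateGeometryError(str(exc)) from exc
        self.lattice = lattice

    @property
    def simplices(self) -> np.ndarray:
        """(n_simplices, 3) vertex indices into the lattice positions."""
        return self._dt.simplices

    @property
    def n_simplices(self) -> int:
        return self._dt.simplices.shape[0]

    def find_simplex(self, points: np.ndarray) -> np.ndarray:
        """Index of the enclosing simplex per query point, -1 outside the hull."""
        return self._dt.find_simplex(np.asarray(points, dtype=float))

    def barycentric(self, points: np.ndarray, simplex_idx: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of ``points`` w.r.t. their given simplices."""
        points = np.asarray(points, dtype=float)
        T = self._dt.transform[simplex_idx]  # (m, 3, 2)
        b = np.einsum("mij,mj->mi", T[:, :2, :], points - T[:, 2, :])
        return np.concatenate([b, 1.0 - b.sum(axis=1, keepdims=True)], axis=1)


def generate_fibre_lattice(
    n_fibres: int,
    fov_radius: float,
    fov_center: tuple[float, float] | None = None,
    jitter_frac: float = 0.25,
    seed: int = 0,
) -> FibreLattice:
    """Synthesise a jittered-hexagonal fibre lattice inside a circular FoV.

    A hexagonal packing is scaled so that at least ``n_fibres`` sites fall
    inside the disc, each site is displaced by an independent uniform jitter
    of magnitude at most ``jitter_frac`` times the lattice pitch, and the
    ``n_fibres`` sites closest to the FoV centre are kept.  Real bundles
    are near-hexagonally packed with manufacturing irregularity; the jitter
    fraction controls that irregularity.

    Deterministic for fixed arguments.
    """
    if n_fibres < 3:
        raise InvalidArgumentError("n_fibres must be >= 3")
    if fov_radius <= 0:
        raise InvalidArgumentError("fov_radius must be positive")
    if not (0.0 <= jitter_frac <= 0.5):
        raise InvalidArgumentError("jitter_frac must lie in [0, 0.5]")
    if fov_center is None:
        fov_center = (float(fov_radius), float(fov_radius))

    # Unit-pitch hexagonal lattice; s = fov_radius / pitch.  The in-disc
    # site count is monotone in s, so bisect for the smallest s covering
    # n_fibres sites.
    def hex_points(radius_units: float) -> np.ndarray:
        jmax = int(np.ceil(radius_units / _SQRT3_2)) + 1
        imax = int(np.ceil(radius_units)) + 1
        jj, ii = np.meshgrid(np.arange(-jmax, jmax + 1), np.arange(-imax, imax + 1), indexing="ij")
        x = ii + 0.5 * (jj & 1)
        y = jj * _SQRT3_2
        return np.stack([y.ravel(), x.ravel()], axis=1)  # (row, col) order

    def count_inside(s: float) -> int:
        pts = hex_points(s)
        return int(np.count_nonzero((pts**2).sum(axis=1) <= s * s))

    s_lo, s_hi = 0.0, np.sqrt(n_fibres * _SQRT3_2 / np.pi) + 2.0
    while count_inside(s_hi) < n_fibres:
        s_hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (s_lo + s_hi)
        if count_inside(mid) >= n_fibres:
            s_hi = mid
        else:
            s_lo = mid
    s = s_hi
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        cand = hex_points(s + 2.0 * jitter_frac + 0.5)
        if jitter_frac > 0:
            # uniform draw in a disc of radius jitter_frac (unit-pitch coords)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=cand.shape[0])
            rad = jitter_frac * np.sqrt(rng.uniform(0.0, 1.0, size=cand.shape[0]))
            cand = cand + np.stack([rad * np.sin(theta), rad * np.cos(theta)], axis=1)
        r2 = (cand**2).sum(axis=1)
        inside = cand[r2 <= s * s]
        if inside.shape[0] >= n_fibres:
            break
        s *= 1.02  # jitter drained the rim; widen slightly and retry
    else:  # pragma: no cover
        raise RuntimeError("lattice generation failed to cover the FoV")
    pitch = fov_radius / s

    d2 = (inside**2).sum(axis=1)
    order = np.lexsort((inside[:, 1], inside[:, 0], d2))
    kept = inside[order[:n_fibres]]
    positions = np.asarray(fov_center, dtype=float) + pitch * kept
    return FibreLattice(
        positions=positions,
        fov_center=(float(fov_center[0]), float(fov_center[1])),
        fov_radius=float(fov_radius),
        seed=seed,
        generator_params={"n_fibres": n_fibres, "jitter_frac": jitter_frac},
    )


def fov_mask(lattice: FibreLattice, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask, true where the pixel centre lies inside the FoV disc."""
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise InvalidArgumentError("grid_shape must be positive")
    rr, cc = np.ogrid[0:rows, 0:cols]
    r0, c0 = lattice.fov_center
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= lattice.fov_radius**2


def nearest_fibre_map(lattice: FibreLattice, grid_shape: tuple[int, int]) -> PixelAssignment:
    """Assign every in-FoV pixel centre to its nearest fibre (Voronoi partition).

    Distance ties are broken towards the lowest fibre index so the map is
    independent of spatial-index internals.  Out-of-FoV pixels get ``-1``.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise InvalidArgumentError("grid_shape must be positive")
    mask = fov_mask(lattice, grid_shape)
    assignment = np.full(grid_shape, -1, dtype=np.int64)
    pts = np.argwhere(mask).astype(float)
    if pts.size == 0:
        return PixelAssignment(grid_shape, assignment, lattice.n_fibres)
    tree = cKDTree(lattice.positions)
    k = min(2, lattice.n_fibres)
    d, idx = tree.query(pts, k=k)
    if k == 1:
        nearest = idx
    else:
        nearest = idx[:, 0].copy()
        tied = d[:, 0] == d[:, 1]
        if np.any(tied):
            # exact ties are rare; resolve them by exhaustive lowest-index argmin
            diff = pts[tied, None, :] - lattice.positions[None, :, :]
            nearest[tied] = np.argmin((diff**2).sum(axis=2), axis=1)
    assignment[mask] = nearest
    return PixelAssignment(grid_shape, assignment, lattice.n_fibres)


def triangulate(lattice: FibreLattice) -> Triangulation:
    """Delaunay-triangulate the fibre positions."""
    return Triangulation(lattice)


def save_lattice(lattice: FibreLattice, path: str | Path) -> None:
    payload = {
        "positions": lattice.positions.tolist(),
        "fov_center": list(lattice.fov_center),
        "fov_radius": lattice.fov_radius,
        "seed": lattice.seed,
        "generator_params": lattice.generator_params,
    }
    Path(path).write_text(json.dumps(payload))


def load_lattice(path: str | Path) -> FibreLattice:
    payload = json.loads(Path(path).read_text())
    return FibreLattice(
        positions=np.asarray(payload["positions"], dtype=float),
        fov_center=tuple(payload["fov_center"]),
        fov_radius=float(payload["fov_radius"]),
        seed=payload.get("seed"),
        generator_params=payload.get("generator_params", {}),
    )
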