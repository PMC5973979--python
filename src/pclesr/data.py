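"""Paired LR/HR datasets: preprocessing, patching, splitting, building.

The training protocol standardises each pair by the LR frame's in-FoV
statistics, rescales every frame individually to [0, 1], cuts
non-overlapping 64x64 patches restricted to the field of view, and splits
pairs 70/15/15 stratified by tissue label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateInputError, InvalidArgumentError
from .image import CartesianImage, load_image, save_image
from .lattice import generate_fibre_lattice, load_lattice, save_lattice, triangulate
from .phantom import generate_phantom_hr, stratum_params
from .reconstruct import simulate_lr
from .signals import NoiseParams

__all__ = [
    "ImagePair",
    "PatchSet",
    "DatasetConfig",
    "standardize_pair",
    "rescale_unit",
    "preprocess_pair",
    "extract_patches",
    "split_dataset",
    "build_dataset",
    "load_dataset",
]


@dataclass
class ImagePair:
    """Aligned LR/HR frames; the LR was derived from the HR by simulation."""

    lr: CartesianImage
    hr: CartesianImage
    pair_id: str = ""
    stratum: str = ""

    def __post_init__(self):
        if self.lr.grid_shape != self.hr.grid_shape:
            raise InvalidArgumentError("lr and hr grids must match")
        if not np.array_equal(self.lr.fov_mask, self.hr.fov_mask):
            raise InvalidArgumentError("lr and hr FoV masks must match")


@dataclass
class PatchSet:
    """Aligned LR/HR training patches cut at identical locations.

    ``lr_patches`` and ``hr_patches`` are ``(n, ps, ps)`` arrays;
    ``positions`` holds the (row, col) top-left corner of each patch in
    its source frame and ``pair_ids`` the source frame per patch.
    """

    lr_patches: np.ndarray
    hr_patches: np.ndarray
    positions: np.ndarray
    pair_ids: list[str]
    patch_size: int = 64

    def __len__(self) -> int:
        return self.lr_patches.shape[0]

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        if not sets:
            raise InvalidArgumentError("cannot concatenate zero patch sets")
        ps = sets[0].patch_size
        return PatchSet(
            lr_patches=np.concatenate([s.lr_patches for s in sets]),
            hr_patches=np.concatenate([s.hr_patches for s in sets]),
            positions=np.concatenate([s.positions for s in sets]),
            pair_ids=[p for s in sets for p in s.pair_ids],
            patch_size=ps,
        )


def standardize_pair(pair: ImagePair, stats: str = "frame",
                     mean_std: tuple[float, float] | None = None) -> ImagePair:
    """Shift/scale both frames by the LR frame's in-FoV mean and std.

    After the transform the LR frame has in-FoV mean 0 and std 1; the HR
    frame is mapped by the same affine transform so the pair stays
    photometrically aligned.  ``stats='frame'`` (default) uses this pair's
    LR statistics; pass ``mean_std`` to standardise with externally
    computed (e.g. training-set-global) statistics.
    """
    if mean_std is not None:
        mu, sd = mean_std
    elif stats == "frame":
        vals = pair.lr.in_fov()
        mu, sd = float(vals.mean()), float(vals.std())
    else:
        raise InvalidArgumentError("stats must be 'frame' or mean_std must be given")
    # relative tolerance: the std of a numerically constant frame is ~1e-17
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateInputError("constant LR frame cannot be standardised")

    def apply(img: CartesianImage) -> CartesianImage:
        out = np.zeros_like(img.pixels)
        out[img.fov_mask] = (img.pixels[img.fov_mask] - mu) / sd
        return img.with_pixels(out, {"standardized": {"mean": mu, "std": sd}})

    return ImagePair(lr=apply(pair.lr), hr=apply(pair.hr),
                     pair_id=pair.pair_id, stratum=pair.stratum)


def rescale_unit(image: CartesianImage) -> CartesianImage:
    """Affinely map the in-FoV range of one frame to [0, 1]; idempotent."""
    vals = image.in_fov()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateInputError("constant frame cannot be rescaled to [0, 1]")
    out = np.zeros_like(image.pixels)
    out[image.fov_mask] = (image.pixels[image.fov_mask] - lo) / (hi - lo)
    return image.with_pixels(out, {"rescaled_unit": True})


def preprocess_pair(pair: ImagePair) -> ImagePair:
    """Full preprocessing: standardise by LR stats, then rescale each frame."""
    std = standardize_pair(pair)
    return ImagePair(lr=rescale_unit(std.lr), hr=rescale_unit(std.hr),
                     pair_id=pair.pair_id, stratum=pair.stratum)


def extract_patches(pair: ImagePair, patch_size: int = 64, coverage: float = 1.0) -> PatchSet:
    """Cut non-overlapping square patches restricted to the field of view.

    Tiles are laid out from the top-left corner of the FoV bounding box
    (so the yield is invariant to grid padding); a tile is kept iff the
    fraction of its pixels inside the FoV is at least ``coverage``.
    LR and HR patches are cut at identical locations.
    """
    rows, cols = pair.lr.grid_shape
    if patch_size > min(rows, cols):
        raise InvalidArgumentError("patch_size exceeds the grid")
    mask = pair.lr.fov_mask
    nz = np.argwhere(mask)
    lr_p, hr_p, pos = [], [], []
    if nz.size:
        r0, c0 = nz.min(axis=0)
        r1, c1 = nz.max(axis=0) + 1
        for r in range(r0, r1 - patch_size + 1, patch_size):
            for c in range(c0, c1 - patch_size + 1, patch_size):
                frac = mask[r : r + patch_size, c : c + patch_size].mean()
                if frac >= coverage:
                    lr_p.append(pair.lr.pixels[r : r + patch_size, c : c + patch_size])
                    hr_p.append(pair.hr.pixels[r : r + patch_size, c : c + patch_size])
                    pos.append((r, c))
    n = len(lr_p)
    return PatchSet(
        lr_patches=np.stack(lr_p) if n else np.empty((0, patch_size, patch_size)),
        hr_patches=np.stack(hr_p) if n else np.empty((0, patch_size, patch_size)),
        positions=np.asarray(pos, dtype=int).reshape(n, 2),
        pair_ids=[pair.pair_id] * n,
        patch_size=patch_size,
    )


def split_dataset(
    pairs: list[ImagePair],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[ImagePair], list[ImagePair], list[ImagePair]]:
    """Stratified train/validation/test split.

    Within each stratum the pairs are shuffled deterministically and
    allotted to the three splits with largest-remainder rounding, so the
    proportions match ``fractions`` up to rounding and every stratum is
    represented proportionally in every split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[ImagePair]] = {}
    for p in pairs:
        strata.setdefault(p.stratum, []).append(p)
    splits: tuple[list[ImagePair], ...] = ([], [], [])
    for label in sorted(strata):
        group = strata[label]
        order = rng.permutation(len(group))
        exact = np.asarray(fractions) * len(group)
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for k in np.argsort(-remainder, kind="stable")[: len(group) - counts.sum()]:
            counts[k] += 1
        start = 0
        for s, cnt in zip(splits, counts):
            s.extend(group[i] for i in order[start : start + cnt])
            start += cnt
    return splits


def save_patchset(patches: PatchSet, path: str | Path) -> None:
    """Write a patch archive: NPZ arrays plus a JSON index sidecar."""
    path = Path(path)
    np.savez_compressed(path, lr=patches.lr_patches, hr=patches.hr_patches,
                        positions=patches.positions)
    path.with_suffix(".json").write_text(json.dumps(
        {"patch_size": patches.patch_size, "pair_ids": patches.pair_ids}))


def load_patchset(path: str | Path) -> PatchSet:
    path = Path(path)
    index = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        return PatchSet(lr_patches=z["lr"], hr_patches=z["hr"], positions=z["positions"],
                        pair_ids=index["pair_ids"], patch_size=index["patch_size"])


def build_patchset(
    pairs: list[ImagePair],
    patch_size: int = 64,
    coverage: float = 1.0,
    preprocess: bool = True,
) -> PatchSet:
    """Preprocess pairs and pool their training patches."""
    sets = []
    for pair in pairs:
        p = preprocess_pair(pair) if preprocess else pair
        sets.append(extract_patches(p, patch_size=patch_size, coverage=coverage))
    return PatchSet.concatenate(sets)


@dataclass
class DatasetConfig:
    """Configuration of a synthetic paired dataset."""

    n_pairs: int = 60
    grid_shape: tuple[int, int] = (256, 256)
    n_fibres: int = 600
    fov_radius: float = 120.0
    jitter_frac: float = 0.25
    n_blobs: int = 150
    sigma_m: float = 0.05
    sigma_a_coeff: float = 0.01
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    strata: tuple[str, ...] = ("colon", "oesophagus")
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "DatasetConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = DatasetConfig(**{k: v for k, v in raw.items()})
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.fractions = tuple(cfg.fractions)
        cfg.strata = tuple(cfg.strata)
        return cfg

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "grid_shape": list(self.grid_shape),
            "n_fibres": self.n_fibres,
            "fov_radius": self.fov_radius,
            "jitter_frac": self.jitter_frac,
            "n_blobs": self.n_blobs,
            "sigma_m": self.sigma_m,
            "sigma_a_coeff": self.sigma_a_coeff,
            "fractions": list(self.fractions),
            "strata": list(self.strata),
            "seed": self.seed,
        }


def _derived_seed(master: int, *tags: int) -> int:
    """Deterministic 31-bit child seed, independent of generation order."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2**31))


def generate_pairs(config: DatasetConfig, lattice=None, tri=None) -> list[ImagePair]:
    """Generate phantom HR frames and their simulated LR partners in memory."""
    rows, cols = config.grid_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if lattice is None:
        lattice = generate_fibre_lattice(
            config.n_fibres, config.fov_radius, center,
            jitter_frac=config.jitter_frac, seed=_derived_seed(config.seed, 0),
        )
    if tri is None:
        tri = triangulate(lattice)
    pairs = []
    for i in range(config.n_pairs):
        stratum = config.strata[i % len(config.strata)]
        hr = generate_phantom_hr(
            config.grid_shape, lattice.fov_center, lattice.fov_radius,
            n_blobs=config.n_blobs, texture_params=stratum_params(stratum),
            seed=_derived_seed(config.seed, 1, i),
        )
        noise = NoiseParams(config.sigma_m, config.sigma_a_coeff,
                            seed=_derived_seed(config.seed, 2, i))
        lr = simulate_lr(hr, lattice, noise, tri=tri)
        pairs.append(ImagePair(lr=lr, hr=hr, pair_id=f"pair{i:04d}", stratum=stratum))
    return pairs


def build_dataset(config: DatasetConfig, out_dir: str | Path) -> Path:
    """Materialise a paired dataset on disk.

    Layout: ``<root>/{train,val,test}/<pair_id>_{lr,hr}.tiff`` plus
    ``manifest.json`` and ``lattice.json``.  Rebuilding with the same
    config yields an identical manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = config.grid_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    lattice = generate_fibre_lattice(
        config.n_fibres, config.fov_radius, center,
        jitter_frac=config.jitter_frac, seed=_derived_seed(config.seed, 0),
    )
    save_lattice(lattice, out / "lattice.json")
    tri = triangulate(lattice)
    pairs = generate_pairs(config, lattice=lattice, tri=tri)
    train, val, test = split_dataset(pairs, config.fractions, seed=_derived_seed(config.seed, 3))
    membership = {p.pair_id: name for name, grp in
                  zip(("train", "val", "test"), (train, val, test)) for p in grp}
    records = []
    for pair in pairs:
        split = membership[pair.pair_id]
        d = out / split
        d.mkdir(exist_ok=True)
        lr_path = d / f"{pair.pair_id}_lr.tiff"
        hr_path = d / f"{pair.pair_id}_hr.tiff"
        save_image(pair.lr, lr_path)
        save_image(pair.hr, hr_path)
        records.append(
            {
                "pair_id": pair.pair_id,
                "stratum": pair.stratum,
                "split": split,
                "lr": str(lr_path.relative_to(out)),
                "hr": str(hr_path.relative_to(out)),
                "noise_seed": pair.lr.meta["noise_params"]["seed"],
            }
        )
    manifest = {
        "schema_version": 1,
        "config": config.to_dict(),
        "lattice": "lattice.json",
        "pairs": records,
    }
    text = json.dumps(manifest, sort_keys=True, indent=1)
    (out / "manifest.json").write_text(text)
    return out


def manifest_hash(dataset_dir: str | Path) -> str:
    """SHA-256 of the manifest text (reproducibility check)."""
    return hashlib.sha256((Path(dataset_dir) / "manifest.json").read_bytes()).hexdigest()


def load_dataset(dataset_dir: str | Path) -> dict[str, list[ImagePair]]:
    """Reload a built dataset into per-split lists of pairs."""
    root = Path(dataset_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    out: dict[str, list[ImagePair]] = {"train": [], "val": [], "test": []}
    for rec in manifest["pairs"]:
        pair = ImagePair(
            lr=load_image(root / rec["lr"]),
            hr=load_image(root / rec["hr"]),
            pair_id=rec["pair_id"],
            stratum=rec["stratum"],
        )
        out[rec["split"]].append(pair)
    return out
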