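"""Phantoms, preprocessing, patch extraction, splitting, dataset building."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pclesr as P
from pclesr.data import DatasetConfig, build_dataset, manifest_hash
from pclesr.errors import DegenerateInputError, InvalidArgumentError
from scipy.ndimage import gaussian_filter


class TestPhantom:
    def test_flat_background(self):
        tp = P.TextureParams(base_level=0.5, background_amp=0.0)
        img = P.generate_phantom_hr((64, 64), (31.5, 31.5), 28.0, n_blobs=0,
                                    texture_params=tp, seed=0)
        assert np.allclose(img.in_fov(), 0.5)
        assert np.all(img.pixels[~img.fov_mask] == 0.0)

    def test_seed_determinism(self):
        a = P.generate_phantom_hr((64, 64), (31.5, 31.5), 28.0, n_blobs=25, seed=3)
        b = P.generate_phantom_hr((64, 64), (31.5, 31.5), 28.0, n_blobs=25, seed=3)
        assert np.array_equal(a.pixels, b.pixels)

    def test_histogram_support_and_contrast(self):
        img = P.generate_phantom_hr((256, 256), (127.5, 127.5), 120.0, n_blobs=150, seed=1)
        vals = img.in_fov()
        assert vals.min() <= 0.05 and vals.max() >= 0.95
        # blur inside the FoV only (normalised convolution), so the rim does
        # not darken against the zeros outside the mask
        m = img.fov_mask.astype(float)
        smooth = gaussian_filter(img.pixels * m, 3.0) / np.maximum(gaussian_filter(m, 3.0), 1e-12)
        blurred = img.with_pixels(np.clip(np.where(img.fov_mask, smooth, 0.0), 0, 1))
        assert P.gcf(img) > P.gcf(blurred)


class TestStandardize:
    def test_lr_moments_after(self, phantom_pair):
        out = P.standardize_pair(phantom_pair)
        vals = out.lr.in_fov()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_hr_uses_lr_statistics(self, phantom_pair):
        out = P.standardize_pair(phantom_pair)
        mu = phantom_pair.lr.in_fov().mean()
        sd = phantom_pair.lr.in_fov().std()
        expected = (phantom_pair.hr.in_fov() - mu) / sd
        assert np.allclose(out.hr.in_fov(), expected)

    def test_identical_frames_stay_identical(self, phantom_pair):
        pair = P.ImagePair(lr=phantom_pair.lr, hr=phantom_pair.lr, pair_id="x", stratum="colon")
        out = P.standardize_pair(pair)
        assert np.allclose(out.lr.pixels, out.hr.pixels)

    def test_constant_frame_rejected(self, small_lattice, small_grid):
        mask = P.fov_mask(small_lattice, small_grid)
        flat = P.CartesianImage(np.full(small_grid, 0.4), mask)
        with pytest.raises(DegenerateInputError):
            P.standardize_pair(P.ImagePair(lr=flat, hr=flat, pair_id="c", stratum="colon"))


class TestRescaleUnit:
    def test_range_mapping(self, small_lattice, small_grid):
        mask = P.fov_mask(small_lattice, small_grid)
        rng = np.random.default_rng(1)
        px = rng.uniform(-2, 3, small_grid)
        img = P.CartesianImage(px, mask)
        out = P.rescale_unit(img)
        vals = out.in_fov()
        assert vals.min() == 0.0 and vals.max() == 1.0
        assert np.argmin(vals) == np.argmin(img.in_fov())
        assert np.argmax(vals) == np.argmax(img.in_fov())

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        img = P.CartesianImage(rng.uniform(-5, 5, (16, 16)), np.ones((16, 16), bool))
        once = P.rescale_unit(img)
        twice = P.rescale_unit(once)
        assert np.allclose(once.pixels, twice.pixels, atol=1e-12)


class TestExtractPatches:
    def test_full_mask_tiling(self):
        img = P.CartesianImage(np.random.default_rng(0).uniform(0, 1, (256, 256)),
                               np.ones((256, 256), bool))
        pair = P.ImagePair(lr=img, hr=img, pair_id="f", stratum="colon")
        ps = P.extract_patches(pair, patch_size=64, coverage=1.0)
        assert len(ps) == 16

    def test_circular_fov_matches_brute_force(self):
        lat = P.generate_fibre_lattice(600, 120.0, (127.5, 127.5), seed=0)
        mask = P.fov_mask(lat, (256, 256))
        rng = np.random.default_rng(2)
        img = P.CartesianImage(rng.uniform(0, 1, (256, 256)) * mask, mask)
        pair = P.ImagePair(lr=img, hr=img, pair_id="c", stratum="colon")
        ps = P.extract_patches(pair, patch_size=64, coverage=1.0)
        nz = np.argwhere(mask)
        r0, c0 = nz.min(axis=0)
        r1, c1 = nz.max(axis=0) + 1
        expected = [
            (r, c)
            for r in range(r0, r1 - 63, 64)
            for c in range(c0, c1 - 63, 64)
            if mask[r : r + 64, c : c + 64].all()
        ]
        assert sorted(map(tuple, ps.positions)) == sorted(expected)

    def test_zero_coverage_keeps_all_tiles(self):
        lat = P.generate_fibre_lattice(600, 120.0, (127.5, 127.5), seed=0)
        mask = P.fov_mask(lat, (256, 256))
        img = P.CartesianImage(np.zeros((256, 256)), mask)
        pair = P.ImagePair(lr=img, hr=img, pair_id="z", stratum="colon")
        ps = P.extract_patches(pair, patch_size=64, coverage=0.0)
        nz = np.argwhere(mask)
        h = nz[:, 0].max() - nz[:, 0].min() + 1
        w = nz[:, 1].max() - nz[:, 1].min() + 1
        assert len(ps) == (h // 64) * (w // 64)

    def test_lr_hr_cut_identically(self, phantom_pair):
        ps = P.extract_patches(phantom_pair, patch_size=32, coverage=0.5)
        for (r, c), lp, hp in zip(ps.positions, ps.lr_patches, ps.hr_patches):
            assert np.array_equal(lp, phantom_pair.lr.pixels[r : r + 32, c : c + 32])
            assert np.array_equal(hp, phantom_pair.hr.pixels[r : r + 32, c : c + 32])

    def test_patch_too_large(self, phantom_pair):
        with pytest.raises(InvalidArgumentError):
            P.extract_patches(phantom_pair, patch_size=100)


def make_pairs(n, stratum):
    img = P.CartesianImage(np.zeros((8, 8)), np.ones((8, 8), bool))
    return [P.ImagePair(lr=img, hr=img, pair_id=f"{stratum}{i}", stratum=stratum)
            for i in range(n)]


class TestSplitDataset:
    def test_70_15_15(self):
        tr, va, te = P.split_dataset(make_pairs(100, "colon"), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_stratum_balance(self):
        pairs = make_pairs(10, "colon") + make_pairs(10, "oesophagus")
        tr, va, te = P.split_dataset(pairs, seed=1)
        for split in (tr, va, te):
            counts = {"colon": 0, "oesophagus": 0}
            for p in split:
                counts[p.stratum] += 1
            assert counts["colon"] == counts["oesophagus"]

    def test_partition_property(self):
        pairs = make_pairs(23, "colon") + make_pairs(17, "oesophagus")
        tr, va, te = P.split_dataset(pairs, seed=2)
        ids = [p.pair_id for p in tr + va + te]
        assert sorted(ids) == sorted(p.pair_id for p in pairs)
        assert len(set(ids)) == len(ids)

    def test_bad_fractions(self):
        with pytest.raises(InvalidArgumentError):
            P.split_dataset(make_pairs(10, "colon"), fractions=(0.5, 0.2, 0.2))

    def test_deterministic(self):
        pairs = make_pairs(20, "colon")
        a = P.split_dataset(pairs, seed=3)
        b = P.split_dataset(pairs, seed=3)
        assert [[p.pair_id for p in s] for s in a] == [[p.pair_id for p in s] for s in b]


class TestBuildDataset:
    CFG = dict(n_pairs=12, grid_shape=(64, 64), n_fibres=120, fov_radius=28.0, seed=1)

    def test_manifest_and_split_sizes(self, tmp_path):
        root = build_dataset(DatasetConfig(**self.CFG), tmp_path / "ds")
        manifest = json.loads((root / "manifest.json").read_text())
        assert len(manifest["pairs"]) == 12
        sizes = {s: sum(r["split"] == s for r in manifest["pairs"])
                 for s in ("train", "val", "test")}
        assert sizes == {"train": 8, "val": 2, "test": 2}

    def test_rebuild_identical_manifest(self, tmp_path):
        h1 = manifest_hash(build_dataset(DatasetConfig(**self.CFG), tmp_path / "a"))
        h2 = manifest_hash(build_dataset(DatasetConfig(**self.CFG), tmp_path / "b"))
        assert h1 == h2

    def test_roundtrip_pixels(self, tmp_path):
        root = build_dataset(DatasetConfig(**self.CFG), tmp_path / "ds")
        splits = P.load_dataset(root)
        assert sum(len(v) for v in splits.values()) == 12
        pair = splits["train"][0]
        assert pair.lr.grid_shape == (64, 64)
        assert np.array_equal(pair.lr.fov_mask, pair.hr.fov_mask)
        # float32 TIFF roundtrip
        assert np.allclose(pair.hr.in_fov(), np.clip(pair.hr.in_fov(), 0, 1), atol=1e-6)


def test_patchset_archive_roundtrip(tmp_path, phantom_pair):
    from pclesr.data import load_patchset, save_patchset

    ps = P.extract_patches(phantom_pair, patch_size=32, coverage=0.5)
    save_patchset(ps, tmp_path / "patches")
    back = load_patchset(tmp_path / "patches")
    assert np.array_equal(back.lr_patches, ps.lr_patches)
    assert np.array_equal(back.hr_patches, ps.hr_patches)
    assert back.pair_ids == ps.pair_ids and back.patch_size == 32


def test_preprocessing_is_affine_per_frame(phantom_pair):
    """standardize -> rescale composes to one affine map per frame, so it
    equals rescale_unit alone on each frame."""
    pre = P.preprocess_pair(phantom_pair)
    direct_lr = P.rescale_unit(phantom_pair.lr)
    direct_hr = P.rescale_unit(phantom_pair.hr)
    assert np.allclose(pre.lr.pixels, direct_lr.pixels, atol=1e-12)
    assert np.allclose(pre.hr.pixels, direct_hr.pixels, atol=1e-12)
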