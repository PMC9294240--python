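"""Patch extraction: region labelling, augmentation geometry, splits."""

import numpy as np
import pytest

from ezseg import patches, phantom, pipeline
from ezseg.boundaries import BoundaryLineSet, InvalidBoundariesError


def _uniform_boundaries(n_cols, rows):
    return BoundaryLineSet(*(np.full(n_cols, float(r)) for r in rows))


def random_boundaries(rng, n_cols=24, n_rows=40, ez_defined=True):
    ilm = rng.integers(2, 8, size=n_cols).astype(float)
    dinl = ilm + rng.integers(2, 6, size=n_cols)
    ez = dinl + rng.integers(0, 4, size=n_cols).astype(float)
    prpe = ez + rng.integers(1, 5, size=n_cols)
    bm = prpe + rng.integers(0, 4, size=n_cols)
    if not ez_defined:
        ez[:] = np.nan
    elif n_cols > 4:
        ez[rng.choice(n_cols, size=n_cols // 4, replace=False)] = np.nan
    b = BoundaryLineSet(ilm, dinl, ez, prpe, bm)
    assert b.is_valid(n_rows)
    return b


class TestLabelRegions:
    def test_documented_example(self):
        b = _uniform_boundaries(3, (5, 8, 10, 12, 14))
        lm = patches.label_regions(b, 20)
        col = lm[:, 1]
        assert list(np.flatnonzero(col == 1)) == [5, 6, 7]
        assert list(np.flatnonzero(col == 2)) == [8, 9]
        assert list(np.flatnonzero(col == 3)) == [10, 11]
        assert list(np.flatnonzero(col == 4)) == [12, 13, 14]

    def test_missing_ez_extends_class2(self):
        b = _uniform_boundaries(2, (5, 8, 10, 12, 14))
        b.ez[:] = np.nan
        lm = patches.label_regions(b, 20)
        assert list(np.flatnonzero(lm[:, 0] == 2)) == [8, 9, 10, 11]
        assert not (lm == 3).any()

    def test_ordering_violation_raises(self):
        b = _uniform_boundaries(2, (5, 8, 10, 12, 14))
        b.prpe[1] = 9.0   # pRPE above EZ
        with pytest.raises(InvalidBoundariesError):
            patches.label_regions(b, 20)

    def test_roundtrip_on_random_boundaries(self, rng):
        """label_regions and extract_boundaries invert each other
        (100 random boundary sets)."""
        for _ in range(100):
            b = random_boundaries(rng)
            lm = patches.label_regions(b, 40)
            back = pipeline.extract_boundaries(lm)
            assert back == b


class TestExtractUnetPatches:
    @pytest.fixture()
    def scan(self, flat_spec):
        img, lines, labels = phantom.generate_bscan(flat_spec, 0)
        return img, lines, labels

    def test_horizontal_positions_arithmetic(self, scan):
        img, lines, labels = scan
        ps = patches.extract_unet_patches(img[:, :64], labels[:, :64],
                                          lines)
        # floor((64-32)/4)+1 = 9 positions; flat scan: baseline + 5 lines each
        starts = sorted({p[2] for p in ps.provenance})
        assert starts == [0, 4, 8, 12, 16, 20, 24, 28, 32]
        assert len(ps) == 9 * 6

    def test_patch_shape_is_256x32(self, scan):
        img, lines, labels = scan
        ps = patches.extract_unet_patches(img, labels, lines)
        assert ps.images.shape[1:] == (256, 32)
        assert ps.labels.shape == ps.images.shape

    def test_boundary_centred_patches(self, small_geometry):
        g = phantom.ScanGeometry(n_cols=64, n_rows=512, n_lines=5)
        spec = phantom.PhantomSpec.flat(g, rows=(100, 200, 260, 300, 330),
                                        noise_level=0.0)
        img, lines, labels = phantom.generate_bscan(spec, 2)
        ps = patches.extract_unet_patches(img, labels, lines)
        # a patch centred on the EZ line at rows 260 starts at 260-128=132
        assert any(r0 == 132 for (_, r0, _) in ps.provenance)
        # baseline: midpoint of ILM(100)/BM(330) = 215 -> start 87
        assert any(r0 == 87 for (_, r0, _) in ps.provenance)

    def test_label_histogram_matches_source(self, scan):
        img, lines, labels = scan
        ps = patches.extract_unet_patches(img, labels, lines)
        for i in (0, len(ps) // 2, len(ps) - 1):
            _, r0, c0 = ps.provenance[i]
            assert np.array_equal(ps.labels[i], labels[r0:r0 + 256, c0:c0 + 32])

    def test_too_small_image_raises(self, scan):
        img, lines, labels = scan
        with pytest.raises(ValueError):
            patches.extract_unet_patches(img[:100], labels[:100], lines)


class TestExtractSwPatches:
    @pytest.fixture()
    def scan(self, flat_spec):
        img, lines, _ = phantom.generate_bscan(flat_spec, 0)
        return img, lines

    def test_boundary_pixels_get_line_classes(self, scan):
        img, lines = scan
        ps = patches.extract_sw_patches(img, lines, bg_per_column=0)
        # flat scan: every column contributes 5 patches labelled 1..5
        assert len(ps) == img.shape[1] * 5
        assert sorted(set(ps.labels.tolist())) == [1, 2, 3, 4, 5]
        for (sid, r, c), lab in zip(ps.provenance, ps.labels):
            if lab == 3:   # EZ line sits at row 150
                assert r == 150

    def test_background_sampling_respects_guard(self, scan):
        img, lines = scan
        ps = patches.extract_sw_patches(img, lines, bg_per_column=2, seed=5)
        bg = [(r, c) for (sid, r, c), lab in zip(ps.provenance, ps.labels)
              if lab == 0]
        boundary_rows = {50, 120, 150, 170, 180}
        for r, c in bg:
            assert all(abs(r - b) > 1 for b in boundary_rows)

    def test_patch_shape_and_determinism(self, scan):
        img, lines = scan
        a = patches.extract_sw_patches(img, lines, bg_per_column=3, seed=11)
        b = patches.extract_sw_patches(img, lines, bg_per_column=3, seed=11)
        assert a.images.shape[1:] == (33, 33)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.labels, b.labels)

    def test_no_label_disagrees_with_boundaries(self, scan):
        img, lines = scan
        ps = patches.extract_sw_patches(img, lines, bg_per_column=2, seed=3)
        from ezseg.boundaries import LINE_NAMES

        for (sid, r, c), lab in zip(ps.provenance, ps.labels):
            on = 0
            for li, name in enumerate(LINE_NAMES):
                row = lines.line(name)[c]
                if not np.isnan(row) and int(row) == r:
                    on = li + 1
                    break
            assert lab == on


class TestSplitDataset:
    def _set(self, n):
        imgs = np.zeros((n, 4, 4), dtype=np.float32)
        labs = np.arange(n, dtype=np.int8) % 6
        return patches.PatchSet("sw", imgs, labs, [("s", i, 0) for i in range(n)])

    def test_80_20_split(self):
        tr, va = patches.split_dataset(self._set(100), 0.8, seed=0)
        assert len(tr) == 80 and len(va) == 20

    def test_rounding_contract(self):
        tr, va = patches.split_dataset(self._set(5), 0.8, seed=0)
        assert len(tr) == 4 and len(va) == 1

    def test_partition_property(self):
        ps = self._set(37)
        tr, va = patches.split_dataset(ps, 0.8, seed=1)
        got = sorted(p[1] for p in tr.provenance + va.provenance)
        assert got == list(range(37))
        assert not set(p[1] for p in tr.provenance) & set(p[1] for p in va.provenance)

    def test_empty_and_bad_fraction(self):
        with pytest.raises(ValueError):
            patches.split_dataset(self._set(10), 1.5)
        empty = patches.PatchSet("sw", np.zeros((0, 4, 4), np.float32),
                                 np.zeros(0, np.int8))
        with pytest.raises(ValueError):
            patches.split_dataset(empty, 0.8)


class TestPatchSetIO:
    def test_shard_roundtrip(self, tmp_path):
        imgs = np.random.rand(10, 8, 8).astype(np.float32)
        labs = (np.arange(10) % 6).astype(np.int8)
        ps = patches.PatchSet("sw", imgs, labs)
        ps.save(tmp_path / "d", shard_size=4)
        back = patches.PatchSet.load(tmp_path / "d")
        assert back.flavor == "sw"
        assert np.array_equal(back.images, imgs)
        assert np.array_equal(back.labels, labs)
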