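"""Dataset indexing, loading, splitting and paired augmentation contracts."""

import numpy as np
import pytest
from PIL import Image

from mixerseg import (
    AugmentParams,
    ImageMaskPair,
    apply_transform,
    augment_pair,
    index_dataset,
    load_pair,
    split_dataset,
)
from mixerseg.data import DatasetIndex, DatasetRecord, TransformSample, save_pair
from mixerseg.exceptions import ConfigurationError


def _write_png(path, arr):
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def _make_tree(root, spec):
    """spec: {class: [(stem, has_masks list)]}, images are 32x32 ramps."""
    base = (np.arange(1024).reshape(32, 32) % 256).astype(np.uint8)
    for cls, entries in spec.items():
        for stem, mask_suffixes in entries:
            _write_png(root / cls / f"{stem}.png", base)
            for suffix in mask_suffixes:
                mask = np.zeros((32, 32), dtype=np.uint8)
                mask[4:10, 4:10] = 255
                _write_png(root / cls / f"{stem}{suffix}.png", mask)


class TestIndexing:
    def test_counts_and_grouping(self, tmp_path):
        _make_tree(tmp_path, {"benign": [("benign (1)", ["_mask"]), ("benign (2)", ["_mask"])]})
        index = index_dataset(tmp_path)
        assert len(index) == 2
        assert all(len(rec.mask_paths) == 1 for rec in index)

    def test_multiple_masks_group_under_one_image(self, tmp_path):
        _make_tree(tmp_path, {"malignant": [("malignant (1)", ["_mask", "_mask_1"])]})
        index = index_dataset(tmp_path)
        assert len(index) == 1
        assert len(index.records[0].mask_paths) == 2

    def test_indexing_is_deterministic(self, tmp_path):
        _make_tree(tmp_path, {"benign": [("benign (2)", ["_mask"]), ("benign (1)", ["_mask"])],
                              "normal": [("normal (1)", [])]})
        first = index_dataset(tmp_path)
        second = index_dataset(tmp_path)
        assert first == second
        assert [r.image_path.name for r in first] == ["benign (1).png", "benign (2).png", "normal (1).png"]

    def test_orphan_mask_warns_and_is_skipped(self, tmp_path):
        _make_tree(tmp_path, {"benign": [("benign (1)", ["_mask"])]})
        mask = np.zeros((32, 32), dtype=np.uint8)
        _write_png(tmp_path / "benign" / "ghost_mask.png", mask)
        with pytest.warns(UserWarning, match="no parent image"):
            index = index_dataset(tmp_path)
        assert len(index) == 1

    def test_empty_root_is_an_error(self, tmp_path):
        (tmp_path / "benign").mkdir()
        with pytest.raises(ConfigurationError, match="no images"):
            index_dataset(tmp_path)


class TestLoading:
    def test_resize_500_to_128(self, tmp_path):
        img = (np.random.default_rng(0).uniform(0, 255, (500, 500))).astype(np.uint8)
        _write_png(tmp_path / "benign" / "benign (1).png", img)
        mask = np.zeros((500, 500), dtype=np.uint8)
        mask[100:200, 100:200] = 255
        _write_png(tmp_path / "benign" / "benign (1)_mask.png", mask)
        pair = load_pair(index_dataset(tmp_path).records[0], size=128)
        assert pair.image.shape == (128, 128)
        assert pair.mask.shape == (128, 128)
        assert set(np.unique(pair.mask)) <= {0, 1}

    def test_disjoint_masks_union_adds_areas(self, tmp_path):
        a = np.zeros((64, 64), dtype=np.uint8)
        a[0:8, 0:8] = 255
        b = np.zeros((64, 64), dtype=np.uint8)
        b[32:40, 32:48] = 255
        img = np.full((64, 64), 120, dtype=np.uint8)
        _write_png(tmp_path / "benign" / "benign (1).png", img)
        _write_png(tmp_path / "benign" / "benign (1)_mask.png", a)
        _write_png(tmp_path / "benign" / "benign (1)_mask_1.png", b)
        pair = load_pair(index_dataset(tmp_path).records[0], size=64)
        assert pair.mask.sum() == 8 * 8 + 8 * 16

    def test_all_white_mask_loads_as_all_ones(self, tmp_path):
        _write_png(tmp_path / "normal" / "normal (1).png", np.full((32, 32), 99, dtype=np.uint8))
        _write_png(tmp_path / "normal" / "normal (1)_mask.png", np.full((32, 32), 255, dtype=np.uint8))
        pair = load_pair(index_dataset(tmp_path).records[0], size=32)
        np.testing.assert_array_equal(pair.mask, 1)

    def test_missing_mask_synthesises_zero_mask(self, tmp_path):
        _write_png(tmp_path / "normal" / "normal (1).png", np.full((32, 32), 99, dtype=np.uint8))
        pair = load_pair(index_dataset(tmp_path).records[0], size=32)
        np.testing.assert_array_equal(pair.mask, 0)

    def test_unreadable_png_names_the_file(self, tmp_path):
        bad = tmp_path / "benign" / "benign (1).png"
        bad.parent.mkdir(parents=True)
        bad.write_bytes(b"not a png")
        record = DatasetRecord(bad, (), "benign")
        with pytest.raises(OSError, match="benign \\(1\\).png"):
            load_pair(record)

    def test_load_save_load_is_idempotent(self, tmp_path):
        img = (np.random.default_rng(1).uniform(0, 255, (64, 64))).astype(np.uint8)
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:20, 10:30] = 255
        _write_png(tmp_path / "benign" / "benign (1).png", img)
        _write_png(tmp_path / "benign" / "benign (1)_mask.png", mask)
        pair = load_pair(index_dataset(tmp_path).records[0], size=64)
        save_pair(pair, tmp_path / "benign" / "benign (2).png", tmp_path / "benign" / "benign (2)_mask.png")
        again = load_pair(index_dataset(tmp_path).records[1], size=64)
        np.testing.assert_array_equal(pair.image, again.image)
        np.testing.assert_array_equal(pair.mask, again.mask)


def _index_of(n_per_class):
    records = []
    for cls, n in n_per_class.items():
        for i in range(n):
            records.append(DatasetRecord(f"{cls}/{cls} ({i}).png", (), cls))
    return DatasetIndex(tuple(records))


class TestSplitting:
    def test_ten_items_split_eight_two(self):
        train, test = split_dataset(_index_of({"benign": 10}), 0.2, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_same_seed_reproduces_membership(self):
        idx = _index_of({"benign": 20, "malignant": 15, "normal": 15})
        a = split_dataset(idx, 0.2, seed=3)
        b = split_dataset(idx, 0.2, seed=3)
        assert a == b

    def test_split_is_disjoint_and_exhaustive(self):
        idx = _index_of({"benign": 13, "malignant": 9})
        train, test = split_dataset(idx, 0.25, seed=1)
        train_set = {r.image_path for r in train}
        test_set = {r.image_path for r in test}
        assert not train_set & test_set
        assert len(train_set | test_set) == len(idx)

    def test_stratification_within_one_item_of_target(self):
        idx = _index_of({"benign": 25, "malignant": 15, "normal": 10})
        _, test = split_dataset(idx, 0.2, seed=5)
        per_class = {}
        for rec in test:
            per_class[rec.label] = per_class.get(rec.label, 0) + 1
        for cls, total in (("benign", 25), ("malignant", 15), ("normal", 10)):
            assert abs(per_class.get(cls, 0) - 0.2 * total) <= 1

    def test_singleton_class_goes_to_train_with_warning(self):
        idx = _index_of({"benign": 10, "normal": 1})
        with pytest.warns(UserWarning, match="fewer than 2"):
            train, test = split_dataset(idx, 0.2, seed=0)
        assert sum(1 for r in train if r.label == "normal") == 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError, match="test_fraction"):
            split_dataset(_index_of({"benign": 4}), 1.5, seed=0)


@pytest.fixture
def dot_pair():
    """A dark frame with one bright dot and its matching mask."""
    image = np.full((32, 32), 0.2, dtype=np.float32)
    mask = np.zeros((32, 32), dtype=np.uint8)
    image[10:14, 20:24] = 0.9
    mask[10:14, 20:24] = 1
    return ImageMaskPair(image=image, mask=mask)


class TestAugmentation:
    def test_double_flip_restores_bit_exactly(self, dot_pair):
        t = TransformSample(flip_h=True, flip_v=True)
        twice = apply_transform(apply_transform(dot_pair, t), t)
        np.testing.assert_array_equal(twice.image, dot_pair.image)
        np.testing.assert_array_equal(twice.mask, dot_pair.mask)

    def test_integer_shift_equals_roll_with_edge_fill(self, dot_pair):
        t = TransformSample(shift_rows=3.0, shift_cols=-2.0)
        out = apply_transform(dot_pair, t)
        expected = np.zeros_like(dot_pair.mask)
        src = np.pad(dot_pair.mask, 3, mode="edge")
        expected = src[3 - 3 : 3 - 3 + 32, 3 + 2 : 3 + 2 + 32]
        np.testing.assert_array_equal(out.mask, expected)

    def test_zero_magnitude_parameters_are_identity(self, dot_pair):
        out = apply_transform(dot_pair, TransformSample())
        np.testing.assert_array_equal(out.image, dot_pair.image)
        np.testing.assert_array_equal(out.mask, dot_pair.mask)

    def test_mask_stays_binary_and_image_in_range(self, dot_pair, rng):
        params = AugmentParams(seed=0)
        for _ in range(20):
            out = augment_pair(dot_pair, params, rng)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_image_and_mask_move_together(self, dot_pair, rng):
        """The mask centroid tracks the bright dot through the joint transform."""
        params = AugmentParams(seed=0)
        for _ in range(10):
            out = augment_pair(dot_pair, params, rng)
            if out.mask.sum() == 0:
                continue
            my, mx = np.argwhere(out.mask == 1).mean(axis=0)
            bright = out.image > 0.55
            assert bright.sum() > 0
            by, bx = np.argwhere(bright).mean(axis=0)
            assert abs(my - by) <= 1.0 and abs(mx - bx) <= 1.0

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(ConfigurationError, match="shift_frac"):
            AugmentParams(shift_frac=0.5)
        with pytest.raises(ConfigurationError, match="zoom_frac"):
            AugmentParams(zoom_frac=0.3)
        with pytest.raises(ConfigurationError, match="rotation"):
            AugmentParams(rotation_deg=45)
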