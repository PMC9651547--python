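"""Dataset protocol tests: folder I/O, stratified splits, geometric
augmentation, one-vs-rest construction, noise injection, and the synthetic
generator's discriminability (nearest-centroid oracle).
"""

import hashlib
import warnings

import numpy as np
import pytest
from PIL import Image

from htem.datakit import (LabelledDataset, NoiseSpec, Record, SplitSpec,
                          SynthSpec, add_noise, augment_geometric,
                          generate_synthetic_dataset, load_image_folder,
                          make_imbalanced_versions, preprocess,
                          preprocess_batch, split_dataset, write_dataset)


def _write_image(path, value, size=(8, 8)):
    arr = np.full((*size, 3), value, dtype=np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)


def dataset_digest(ds: LabelledDataset) -> str:
    h = hashlib.sha256()
    for i, r in enumerate(ds.records):
        h.update(ds.get_image(i).tobytes())
        h.update(bytes([r.label]))
    return h.hexdigest()


# ---------------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------------

def test_load_image_folder_sorted_and_indexed(tmp_path):
    _write_image(tmp_path / "beta" / "b1.png", 10)
    _write_image(tmp_path / "alpha" / "a2.jpg", 20)
    _write_image(tmp_path / "alpha" / "a1.png", 30)
    ds = load_image_folder(tmp_path)
    assert ds.class_names == ["alpha", "beta"]
    assert [r.uid for r in ds.records] == ["alpha/a1.png", "alpha/a2.jpg",
                                           "beta/b1.png"]
    assert [r.label for r in ds.records] == [0, 0, 1]


def test_mixed_formats_decode_identically(tmp_path):
    for ext in ("png", "tiff", "bmp"):
        _write_image(tmp_path / "c" / f"img.{ext}", 42)
    ds = load_image_folder(tmp_path)
    images = [ds.get_image(i) for i in range(len(ds))]
    for img in images[1:]:
        np.testing.assert_array_equal(img, images[0])


def test_empty_class_directory_skipped_with_warning(tmp_path):
    _write_image(tmp_path / "full" / "x.png", 5)
    (tmp_path / "empty").mkdir()
    with pytest.warns(UserWarning, match="empty"):
        ds = load_image_folder(tmp_path)
    assert ds.class_names == ["full"]


def test_undecodable_file_names_the_culprit(tmp_path):
    bad = tmp_path / "c" / "broken.png"
    bad.parent.mkdir()
    bad.write_bytes(b"not an image at all")
    with pytest.raises(ValueError, match="broken.png"):
        load_image_folder(tmp_path)


def test_write_then_load_roundtrip(tmp_path):
    ds = generate_synthetic_dataset(SynthSpec(n_classes=2, per_class=3,
                                              image_size=16, seed=0))
    write_dataset(ds, tmp_path / "out", seed_note="0")
    loaded = load_image_folder(tmp_path / "out")
    assert len(loaded) == 6
    assert (tmp_path / "out" / "manifest.csv").exists()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_reference_split_counts():
    """21 classes x 40 images at 37.5/25/37.5 gives 315/210/315 overall
    and 15/10/15 per class."""
    ds = generate_synthetic_dataset(SynthSpec(n_classes=21, per_class=40,
                                              image_size=16, seed=3))
    out = split_dataset(ds, SplitSpec(0.375, 0.25, 0.375, seed=1))
    sizes = {s: len(out.subset(s)) for s in ("train", "val", "test")}
    assert sizes == {"train": 315, "val": 210, "test": 315}
    for label in range(21):
        per = [r.split for r in out.records if r.label == label]
        assert (per.count("train"), per.count("val"), per.count("test")) \
            == (15, 10, 15)


def test_split_conserves_records_and_is_disjoint(small_multiclass_dataset):
    ds = small_multiclass_dataset
    n = sum(len(ds.subset(s)) for s in ("train", "val", "test"))
    assert n == len(ds)
    assert all(r.split in ("train", "val", "test") for r in ds.records)


def test_split_deterministic_per_seed():
    ds = generate_synthetic_dataset(SynthSpec(n_classes=3, per_class=8,
                                              image_size=16, seed=5))
    a = split_dataset(ds, SplitSpec(seed=9))
    b = split_dataset(ds, SplitSpec(seed=9))
    assert [r.split for r in a.records] == [r.split for r in b.records]
    c = split_dataset(ds, SplitSpec(seed=10))
    assert [r.split for r in a.records] != [r.split for r in c.records]


def test_split_rejects_undersized_class():
    ds = LabelledDataset([Record(image=np.zeros((4, 4, 3), np.uint8), label=0,
                                 uid="a"),
                          Record(image=np.zeros((4, 4, 3), np.uint8), label=1,
                                 uid="b")],
                         ["a", "b"])
    with pytest.raises(ValueError, match="fewer than"):
        split_dataset(ds, SplitSpec(seed=0))


def test_split_spec_validation():
    with pytest.raises(ValueError):
        SplitSpec(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        SplitSpec(-0.1, 0.6, 0.5)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augmentation_is_exactly_six_fold(tiny_dataset):
    train = tiny_dataset.subset("train")
    aug = augment_geometric(train)
    assert len(aug) == 6 * len(train)
    assert len(augment_geometric(tiny_dataset)) == 6 * len(tiny_dataset)


def test_augmentation_single_image():
    ds = LabelledDataset([Record(image=np.zeros((4, 4, 3), np.uint8),
                                 label=0, uid="x")], ["only"])
    assert len(augment_geometric(ds)) == 6


def test_augmentation_preserves_labels_and_ids_distinct(tiny_dataset):
    aug = augment_geometric(tiny_dataset)
    uids = [r.uid for r in aug.records]
    assert len(uids) == len(set(uids))
    for i in range(len(tiny_dataset)):
        src = tiny_dataset.records[i]
        block = aug.records[6 * i:6 * (i + 1)]
        assert all(r.label == src.label for r in block)
        assert all(r.split == src.split for r in block)


def test_rot90_twice_equals_rot180(rng):
    img = rng.integers(0, 255, size=(6, 8, 3)).astype(np.uint8)
    np.testing.assert_array_equal(np.rot90(np.rot90(img)), np.rot90(img, 2))


# ---------------------------------------------------------------------------
# one-vs-rest imbalance
# ---------------------------------------------------------------------------

def test_one_vs_rest_count_and_positives():
    ds = generate_synthetic_dataset(SynthSpec(n_classes=21, per_class=2,
                                              image_size=16, seed=0))
    versions = make_imbalanced_versions(ds)
    assert len(versions) == 21
    for k, v in enumerate(versions):
        assert len(v) == len(ds)                    # conservation
        positives = sum(r.label for r in v.records)
        assert positives == 2                       # per-class count
        expect = [int(r.label == k) for r in ds.records]
        assert [r.label for r in v.records] == expect


def test_two_class_versions_are_label_swaps(tiny_dataset):
    v0, v1 = make_imbalanced_versions(tiny_dataset)
    for a, b in zip(v0.records, v1.records):
        assert a.label == 1 - b.label


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_zero_noise_is_identity(rng):
    img = rng.random((16, 16, 3))
    np.testing.assert_array_equal(
        add_noise(img, NoiseSpec(kind="salt_pepper", amount=0.0, seed=1)), img)
    np.testing.assert_array_equal(
        add_noise(img, NoiseSpec(kind="gaussian", sigma=0.0, seed=1)), img)


def test_full_salt_pepper_saturates(rng):
    img = rng.random((8, 8, 3))
    out = add_noise(img, NoiseSpec(kind="salt_pepper", amount=1.0, seed=2))
    assert set(np.unique(out)) <= {0.0, 1.0}


def test_salt_pepper_hits_exact_pixel_count(rng):
    img = np.full((20, 20, 3), 0.5)
    spec = NoiseSpec(kind="salt_pepper", amount=0.13, seed=3)
    out = add_noise(img, spec)
    changed = (out != img).any(axis=2).sum()
    assert changed == round(0.13 * 400)


def test_noise_deterministic_per_seed(rng):
    img = rng.random((12, 12, 3))
    spec = NoiseSpec(kind="gaussian", sigma=0.1, seed=8)
    np.testing.assert_array_equal(add_noise(img, spec), add_noise(img, spec))


def test_small_noise_converges_to_identity(rng):
    img = rng.random((10, 10, 3)) * 0.8 + 0.1
    for sigma in (1e-2, 1e-4, 1e-6):
        out = add_noise(img, NoiseSpec(kind="gaussian", sigma=sigma, seed=0))
        assert np.abs(out - img).max() < 10 * sigma


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(kind="salt_pepper", amount=1.5)
    with pytest.raises(ValueError):
        NoiseSpec(kind="gaussian", sigma=-0.1)
    with pytest.raises(ValueError):
        NoiseSpec(kind="speckle")


def test_noise_rejects_unnormalized_image():
    with pytest.raises(ValueError, match="0,1"):
        add_noise(np.full((4, 4), 200.0), NoiseSpec())


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def test_generator_shape_and_balance():
    ds = generate_synthetic_dataset(SynthSpec(n_classes=5, per_class=4,
                                              image_size=32, seed=1))
    assert len(ds) == 20
    assert (ds.class_counts() == 4).all()
    img = ds.get_image(0)
    assert img.shape == (32, 32, 3) and img.dtype == np.uint8


def test_generator_digest_is_pure_function_of_spec():
    spec = SynthSpec(n_classes=3, per_class=4, image_size=24, seed=42)
    assert dataset_digest(generate_synthetic_dataset(spec)) \
        == dataset_digest(generate_synthetic_dataset(spec))
    other = SynthSpec(n_classes=3, per_class=4, image_size=24, seed=43)
    assert dataset_digest(generate_synthetic_dataset(spec)) \
        != dataset_digest(generate_synthetic_dataset(other))


def test_nearest_centroid_oracle_beats_chance():
    """Classes must be discriminable: a pixel-mean nearest-centroid rule
    on half the data classifies the held-out half above 60%."""
    ds = generate_synthetic_dataset(SynthSpec(n_classes=2, per_class=50,
                                              image_size=32, seed=21))
    images = np.stack([ds.get_image(i).astype(float).mean(axis=2) / 255
                       for i in range(len(ds))])
    labels = ds.labels()
    train_idx = np.concatenate([np.where(labels == k)[0][:25] for k in (0, 1)])
    test_idx = np.setdiff1d(np.arange(len(ds)), train_idx)
    centroids = np.stack([images[train_idx][labels[train_idx] == k].mean(axis=0)
                          for k in (0, 1)])
    dists = np.stack([((images[test_idx] - c) ** 2).sum(axis=(1, 2))
                      for c in centroids])
    acc = (dists.argmin(axis=0) == labels[test_idx]).mean()
    assert acc > 0.6


def test_generator_spec_validation():
    with pytest.raises(ValueError):
        SynthSpec(n_classes=1)
    with pytest.raises(ValueError):
        SynthSpec(per_class=0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_resize_then_center_crop(rng):
    img = rng.integers(0, 255, size=(300, 200, 3)).astype(np.uint8)
    out = preprocess(img, 224)
    assert out.shape == (224, 224, 3)
    assert out.dtype == np.float32
    assert 0.0 <= out.min() and out.max() <= 1.0


def test_preprocess_noop_when_sized(rng):
    img = rng.integers(0, 255, size=(224, 224, 3)).astype(np.uint8)
    out = preprocess(img, 224)
    np.testing.assert_allclose(out, img.astype(np.float32) / 255)


def test_preprocess_rejects_bad_side(rng):
    with pytest.raises(ValueError):
        preprocess(rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8), 100)


def test_preprocess_deterministic(tiny_dataset):
    a, ya = preprocess_batch(tiny_dataset.subset("train"), 32)
    b, yb = preprocess_batch(tiny_dataset.subset("train"), 32)
    np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(ya, yb)
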