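"""Synthetic fixture generators: determinism, regime contracts, splits,
and the doubling augmentation policy."""

import numpy as np
import pytest
from PIL import Image

from seafec.fixtures import (
    AugmentationPolicy,
    augment_double,
    gen_classification_fixture,
    gen_detection_fixture,
    gen_segmentation_fixture,
    mask_to_pseudocolor,
    pseudocolor_to_mask,
    save_fixture,
    split_samples,
)


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def test_classification_fixture_is_balanced():
    samples = gen_classification_fixture(10, image_size=32, seed=3)
    labels = [s.label for s in samples]
    assert len(samples) == 20
    assert labels.count(0) == labels.count(1) == 10


def test_classification_fixture_deterministic_under_seed():
    a = gen_classification_fixture(3, image_size=32, seed=7)
    b = gen_classification_fixture(3, image_size=32, seed=7)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.image, sb.image)
    c = gen_classification_fixture(3, image_size=32, seed=8)
    assert any((sa.image != sc.image).any() for sa, sc in zip(a, c))


def test_spot_lesions_cover_fewer_pixels_than_strips():
    """Separation oracle over 100 seeded samples: strip-class streaks
    occupy a larger pixel fraction than spot-class blobs."""
    samples = gen_classification_fixture(50, image_size=32, seed=11)
    spot = np.mean([s.meta["lesion_fraction"] for s in samples if s.label == 0])
    strip = np.mean([s.meta["lesion_fraction"] for s in samples if s.label == 1])
    assert spot < strip


def test_classification_parameter_validation():
    with pytest.raises(ValueError):
        gen_classification_fixture(10, image_size=8)
    with pytest.raises(ValueError):
        gen_classification_fixture(0)


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def test_segmentation_masks_use_three_classes():
    samples = gen_segmentation_fixture(10, image_size=32, seed=5)
    for s in samples:
        assert set(np.unique(s.mask)) <= {0, 1, 2}
    union = set(np.concatenate([np.unique(s.mask) for s in samples]))
    assert union == {0, 1, 2}


def test_weed_share_tracks_requested_fraction():
    samples = gen_segmentation_fixture(50, image_size=32, weed_fraction=0.05, seed=2)
    mean_share = np.mean([(s.mask == 2).mean() for s in samples])
    assert 0.025 <= mean_share <= 0.075


def test_pseudocolor_round_trip_is_identity():
    mask = gen_segmentation_fixture(1, image_size=32, seed=0)[0].mask
    rgb = mask_to_pseudocolor(mask)
    np.testing.assert_array_equal(pseudocolor_to_mask(rgb), mask)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------

def test_sparse_regime_box_counts():
    for s in gen_detection_fixture(5, image_size=48, density="sparse", seed=1):
        assert 1 <= len(s.boxes) <= 3


def test_dense_regime_many_small_boxes():
    dense = gen_detection_fixture(25, image_size=48, density="dense", seed=1)
    sparse = gen_detection_fixture(25, image_size=48, density="sparse", seed=1)
    for s in dense:
        assert len(s.boxes) >= 10
    area = lambda b: (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    med_dense = np.median(np.concatenate([area(s.boxes) for s in dense]))
    med_sparse = np.median(np.concatenate([area(s.boxes) for s in sparse]))
    assert med_dense < med_sparse


def test_boxes_lie_inside_image():
    for s in gen_detection_fixture(10, image_size=48, density="dense", seed=9):
        b = s.boxes
        assert (b[:, 0] < b[:, 2]).all() and (b[:, 1] < b[:, 3]).all()
        assert b[:, [0, 1]].min() >= 0 and b[:, [2, 3]].max() <= 48


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

def test_doubling_doubles_every_class():
    samples = gen_classification_fixture(7, image_size=32, seed=0)
    doubled = augment_double(samples, seed=1)
    assert len(doubled) == 2 * len(samples)
    labels = [s.label for s in doubled]
    assert labels.count(0) == labels.count(1) == 14
    assert augment_double([], seed=0) == []


def test_rotation_preserves_mask_histogram():
    sample = gen_segmentation_fixture(1, image_size=32, seed=4)[0]
    policy = AugmentationPolicy(operations=("rotation",), rotation_angles=(90.0,))
    doubled = augment_double([sample], policy, seed=0)
    orig, rot = doubled[0].mask, doubled[1].mask
    for c in (0, 1, 2):
        assert (orig == c).sum() == (rot == c).sum()


def test_augmented_boxes_stay_in_bounds():
    samples = gen_detection_fixture(6, image_size=48, density="sparse", seed=3)
    doubled = augment_double(samples, seed=5)
    for s in doubled:
        if len(s.boxes):
            assert s.boxes[:, [0, 1]].min() >= 0
            assert s.boxes[:, [2, 3]].max() <= 48
            assert (s.boxes[:, 2] > s.boxes[:, 0]).all()


def test_policy_requires_an_operation():
    with pytest.raises(ValueError):
        AugmentationPolicy(operations=())


# ----------------------------------------------------------------------
# splits and I/O
# ----------------------------------------------------------------------

@pytest.mark.parametrize("ratios,names", [
    ((0.7, 0.2, 0.1), ("train", "val", "test")),
    ((0.6, 0.2, 0.2), ("train", "val", "test")),
])
def test_splits_partition_exactly(ratios, names):
    samples = gen_classification_fixture(20, image_size=32, seed=0)
    splits = split_samples(samples, ratios, seed=1, names=names)
    sizes = {k: len(v) for k, v in splits.items()}
    assert sum(sizes.values()) == len(samples)
    ids = [id(s) for split in splits.values() for s in split]
    assert len(set(ids)) == len(samples)  # disjoint
    # per-class floor rounding with remainder to train
    per_class = 20
    expect_val = int(np.floor(ratios[1] * per_class)) * 2
    assert sizes["val"] == expect_val


def test_save_fixture_writes_pngs_and_json(tmp_path):
    samples = gen_segmentation_fixture(4, image_size=32, seed=0)
    splits = split_samples(samples, (0.6, 0.2, 0.2), seed=0)
    save_fixture(tmp_path, splits)
    mask_files = sorted((tmp_path / "train").glob("*_mask.png"))
    assert mask_files
    loaded = np.asarray(Image.open(mask_files[0]).convert("P"))
    assert set(np.unique(loaded)) <= {0, 1, 2}
    assert (tmp_path / "train" / "annotations.json").exists()
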