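"""CT preparation chain: windowing, slicing, filtering, ROI crop, resize,
split arithmetic, augmentation, NIfTI round trips."""

import numpy as np
import pytest

from stcunet.preprocess import (
    AugmentConfig,
    SliceSample,
    WindowSpec,
    apply_window,
    augment,
    crop_roi,
    filter_positive,
    load_volume,
    read_manifest,
    resize_to,
    run_pipeline,
    slice_volume,
    split_by_case,
    split_dataset,
    write_dataset,
    load_sample,
)
from stcunet.synthetic import PhantomParams, make_phantom_volume, write_phantom_case


@pytest.fixture(scope="module")
def phantom_case(tmp_path_factory):
    params = PhantomParams(size=64)
    vol, lab = make_phantom_volume(params, depth=10, rng=np.random.default_rng(3),
                                   tumor_slices=(3, 8))
    case_dir = tmp_path_factory.mktemp("cases") / "case_00000"
    write_phantom_case(vol, lab, case_dir)
    return vol, lab, case_dir


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def test_window_analytic_endpoints():
    spec = WindowSpec(width=400, level=40)
    hu = np.array([-160.0, 240.0, 40.0, -1000.0, 3000.0])
    out = apply_window(hu, spec)
    assert np.allclose(out, [0.0, 1.0, 0.5, 0.0, 1.0])


def test_window_is_monotone_and_matches_scalar_loop(rng):
    spec = WindowSpec(width=350, level=50)
    hu = rng.uniform(-500, 500, size=(6, 6))
    out = apply_window(hu, spec)
    assert out.min() >= 0.0 and out.max() <= 1.0
    lo = spec.level - spec.width / 2
    for i in range(6):
        for j in range(6):
            expected = min(max((hu[i, j] - lo) / spec.width, 0.0), 1.0)
            assert out[i, j] == pytest.approx(expected, abs=1e-12)
    order = np.argsort(hu.ravel())
    assert (np.diff(out.ravel()[order]) >= -1e-12).all()


def test_window_idempotent_on_rescaled_output(rng):
    spec = WindowSpec(width=400, level=40)
    hu = rng.uniform(-300, 300, size=(5, 5))
    once = apply_window(hu, spec)
    lo = spec.level - spec.width / 2
    again = apply_window(once * spec.width + lo, spec)
    assert np.allclose(once, again, atol=1e-12)


def test_window_requires_positive_width():
    with pytest.raises(ValueError):
        WindowSpec(width=0)


# ---------------------------------------------------------------------------
# slicing / filtering / cropping / resizing
# ---------------------------------------------------------------------------

def _binary_labels(lab):
    from dataclasses import replace
    return replace(lab, voxels=(lab.voxels == 2).astype(np.uint8))


def test_slice_volume_order_and_identity(phantom_case):
    vol, lab, _ = phantom_case
    slices = slice_volume(vol, _binary_labels(lab))
    assert len(slices) == 10
    assert [s.slice_index for s in slices] == list(range(10))
    for k, s in enumerate(slices):
        assert np.array_equal(s.image, vol.voxels[k])
    stacked = np.stack([s.image for s in slices])
    assert np.array_equal(stacked, vol.voxels)


def test_filter_positive_keeps_known_slab(phantom_case):
    vol, lab, _ = phantom_case
    # raw labels use 0/1/2; the tumor mask is class 2
    kept = filter_positive(slice_volume(vol, _binary_labels(lab)))
    assert [s.slice_index for s in kept] == [3, 4, 5, 6, 7]


def test_filter_positive_degenerate_cases():
    empty = SliceSample(np.zeros((4, 4)), np.zeros((4, 4), dtype=np.uint8))
    full = SliceSample(np.zeros((4, 4)), np.ones((4, 4), dtype=np.uint8))
    assert filter_positive([empty, empty]) == []
    assert filter_positive([full, full]) == [full, full]


def test_crop_roi_single_pixel_and_margin():
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10, 20] = 1
    s = SliceSample(np.arange(32 * 32, dtype=float).reshape(32, 32), mask)
    tight = crop_roi(s, margin=0)
    assert tight.image.shape == (1, 1)
    assert tight.image[0, 0] == 10 * 32 + 20


def test_crop_roi_analytic_with_clipping():
    mask = np.zeros((16, 12), dtype=np.uint8)
    mask[4:7, 2:10] = 1
    s = SliceSample(np.zeros((16, 12)), mask)
    c = crop_roi(s, margin=2)
    assert c.mask.shape == (7, 12)  # rows 2..8, cols 0..11 clipped


def test_crop_roi_idempotent_at_zero_margin(rng):
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[5:9, 7:12] = 1
    s = SliceSample(rng.normal(size=(20, 20)), mask)
    once = crop_roi(s, margin=0)
    twice = crop_roi(once, margin=0)
    assert np.array_equal(once.image, twice.image)


def test_crop_roi_empty_mask_instructs_filtering():
    s = SliceSample(np.zeros((8, 8)), np.zeros((8, 8), dtype=np.uint8))
    with pytest.raises(ValueError, match="filter_positive"):
        crop_roi(s)


def test_resize_identity_and_constant(rng):
    img = rng.random((512, 512))
    mask = (rng.random((512, 512)) < 0.2).astype(np.uint8)
    s = resize_to(SliceSample(img, mask), 512)
    assert np.array_equal(s.image, img)
    const = resize_to(SliceSample(np.full((20, 30), 3.3),
                                  np.ones((20, 30), dtype=np.uint8)), 64)
    assert np.allclose(const.image, 3.3)
    assert const.image.shape == (64, 64)


def test_resize_keeps_mask_binary(rng):
    for _ in range(50):
        h = int(rng.integers(3, 40))
        w = int(rng.integers(3, 40))
        mask = (rng.random((h, w)) < 0.4).astype(np.uint8)
        out = resize_to(SliceSample(rng.random((h, w)), mask), 32)
        assert set(np.unique(out.mask)) <= {0, 1}


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [1, 2, 10, 5327])
def test_split_partitions_cover_disjointly(n):
    split = split_dataset(n, 0.8, seed=11)
    train, test = set(split.train_indices), set(split.test_indices)
    assert train.isdisjoint(test)
    assert train | test == set(range(n))
    assert len(split.train_indices) == int(np.floor(0.8 * n + 0.5))


def test_split_sizes_round_half_up():
    s = split_dataset(10, 0.8, seed=0)
    assert (len(s.train_indices), len(s.test_indices)) == (8, 2)
    s = split_dataset(5327, 0.8, seed=0)
    assert (len(s.train_indices), len(s.test_indices)) == (4262, 1065)


def test_split_seed_determinism():
    a = split_dataset(100, 0.8, seed=5)
    b = split_dataset(100, 0.8, seed=5)
    c = split_dataset(100, 0.8, seed=6)
    assert a == b
    assert a.train_indices != c.train_indices
    assert len(c.train_indices) == 80


def test_split_by_case_keeps_patients_together():
    case_ids = [f"c{i//10}" for i in range(50)]  # 5 cases x 10 slices
    split = split_by_case(case_ids, 0.8, seed=1)
    train_cases = {case_ids[i] for i in split.train_indices}
    test_cases = {case_ids[i] for i in split.test_indices}
    assert train_cases.isdisjoint(test_cases)
    assert len(train_cases) == 4 and len(test_cases) == 1


def test_split_rejects_empty():
    with pytest.raises(ValueError):
        split_dataset(0)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _sample(rng, n=32):
    mask = np.zeros((n, n), dtype=np.uint8)
    mask[8:14, 10:16] = 1
    return SliceSample(np.clip(rng.random((n, n)), 0, 1), mask)


def test_augment_all_probabilities_zero_is_identity(rng):
    cfg = AugmentConfig(p_crop=0, p_hflip=0, p_vflip=0, p_jitter=0)
    s = _sample(rng)
    out = augment(s, cfg, np.random.default_rng(0))
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_double_flip_is_identity(rng):
    cfg = AugmentConfig(p_crop=0, p_hflip=1.0, p_vflip=0, p_jitter=0)
    s = _sample(rng)
    once = augment(s, cfg, np.random.default_rng(1))
    back = augment(once, cfg, np.random.default_rng(1))
    assert np.array_equal(back.image, s.image)
    assert np.array_equal(back.mask, s.mask)


def test_flips_preserve_positive_pixel_count(rng):
    cfg = AugmentConfig(p_crop=0, p_hflip=1.0, p_vflip=1.0, p_jitter=0)
    s = _sample(rng)
    out = augment(s, cfg, np.random.default_rng(2))
    assert out.mask.sum() == s.mask.sum()
    assert out.image.shape == s.image.shape


def test_flip_commutes_with_crop_up_to_reflection(rng):
    s = _sample(rng)
    flipped = SliceSample(s.image[:, ::-1].copy(), s.mask[:, ::-1].copy())
    crop_then_flip = crop_roi(s, margin=2)
    flip_then_crop = crop_roi(flipped, margin=2)
    assert np.array_equal(flip_then_crop.mask, crop_then_flip.mask[:, ::-1])
    assert np.array_equal(flip_then_crop.image, crop_then_flip.image[:, ::-1])


def test_augment_keeps_mask_binary_and_shape(rng):
    cfg = AugmentConfig()
    s = _sample(rng)
    gen = np.random.default_rng(3)
    for _ in range(25):
        out = augment(s, cfg, gen)
        assert out.image.shape == s.image.shape
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0


# ---------------------------------------------------------------------------
# NIfTI round trip + full pipeline
# ---------------------------------------------------------------------------

def test_nifti_write_read_round_trip(phantom_case):
    vol, lab, case_dir = phantom_case
    rvol, rlab = load_volume(case_dir)
    assert rvol.voxels.shape == vol.voxels.shape
    assert np.allclose(rvol.voxels, vol.voxels, atol=1e-5)
    assert np.array_equal(rlab.voxels, (lab.voxels == 2).astype(np.uint8))


def test_load_volume_reorients_to_canonical(tmp_path):
    """A corner voxel tagged in a flipped/permuted orientation must come back
    at the canonical position."""
    import nibabel as nib

    data = np.zeros((6, 7, 8), dtype=np.float32)
    data[0, 0, 0] = 111.0  # tag one corner
    # store with axes permuted to (A, S, R) and the S axis negated
    stored = np.transpose(data, (1, 0, 2))[:, ::-1, :].copy()
    affine = np.array([
        [0.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
        [0.0, -1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    case = tmp_path / "case_x"
    case.mkdir()
    nib.save(nib.Nifti1Image(stored, affine), case / "imaging.nii.gz")
    nib.save(nib.Nifti1Image((stored > 0).astype(np.uint8) * 2, affine),
             case / "segmentation.nii.gz")
    vol, lab = load_volume(case)
    assert vol.voxels.shape == (6, 7, 8)
    assert vol.voxels[0, 0, 0] == pytest.approx(111.0)
    assert lab.voxels[0, 0, 0] == 1


def test_missing_case_file_raises(tmp_path):
    (tmp_path / "empty_case").mkdir()
    with pytest.raises(FileNotFoundError):
        load_volume(tmp_path / "empty_case")


def test_pipeline_counts_and_ranges(phantom_case):
    vol, lab, case_dir = phantom_case
    rvol, rlab = load_volume(case_dir)
    samples = run_pipeline(rvol, rlab, margin=8, size=64)
    assert len(samples) == 5  # the constructed tumor slab
    for s in samples:
        assert s.image.shape == (64, 64)
        assert 0.0 <= s.image.min() and s.image.max() <= 1.0
        assert set(np.unique(s.mask)) <= {0, 1}
        assert s.mask.any()


def test_manifest_write_read_round_trip(tmp_path, rng):
    samples = [
        SliceSample(np.clip(rng.random((32, 32)), 0, 1),
                    (rng.random((32, 32)) < 0.2).astype(np.uint8),
                    case_id=f"c{i}", slice_index=i)
        for i in range(5)
    ]
    manifest = write_dataset(samples, tmp_path / "ds", seed=4)
    rows = read_manifest(manifest)
    assert len(rows) == 5
    assert {r["split"] for r in rows} == {"train", "test"}
    back = load_sample(rows[0])
    orig = samples[0]
    assert np.array_equal(back.mask, orig.mask)
    assert np.abs(back.image - orig.image).max() <= 1.0 / 255.0 + 1e-9
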