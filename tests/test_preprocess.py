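"""Resampling, normalization, mean subtraction and the augmentation branches."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkdvol.preprocess import (AugmentationConfig, ImageVolume, TrainingSlice,
                               augment_deform_intensity, augment_shift,
                               build_training_set, compute_mean_and_subtract,
                               normalize_intensity, resample_slice)


def _slice(image, label=None, tag=("case", 0, "orig")):
    if label is None:
        label = np.zeros_like(image, dtype=np.uint8)
    return TrainingSlice(np.asarray(image, dtype=float), label, tag)


# --------------------------------------------------------------- resample


def test_resample_preserves_constant_images():
    out = resample_slice(np.full((512, 512), 37.0), (224, 224))
    assert out.shape == (224, 224)
    assert np.allclose(out, 37.0, atol=1e-9)


def test_resample_round_trip_error_small_on_smooth_gradient():
    r, c = np.meshgrid(np.linspace(0, 1, 512), np.linspace(0, 1, 512),
                       indexing="ij")
    img = 100 * r + 55 * c
    back = resample_slice(resample_slice(img, (224, 224)), (512, 512))
    assert np.abs(back - img).max() <= 0.02 * np.ptp(img)


def test_resample_identity_when_target_equals_source():
    img = np.random.default_rng(0).random((64, 64))
    assert np.array_equal(resample_slice(img, (64, 64)), img)


def test_resample_nearest_keeps_labels_binary():
    lab = (np.random.default_rng(1).random((128, 128)) > 0.5).astype(np.uint8)
    out = resample_slice(lab, (60, 60), order=0)
    assert set(np.unique(out)) <= {0, 1}


def test_resample_rejects_bad_target():
    with pytest.raises(ValueError):
        resample_slice(np.zeros((16, 16)), (0, 10))


# -------------------------------------------------------------- normalize


def test_normalize_endpoints_and_scale_invariance():
    out = normalize_intensity(np.array([[10.0, 20.0]]))
    assert np.allclose(out, [[0.0, 255.0]])
    for s in (0.5, 3.0):
        out = normalize_intensity(np.array([[0.0, 127.5 * s, 255.0 * s]]))
        assert np.allclose(out, [[0.0, 127.5, 255.0]])
    full = np.linspace(0, 255, 100).reshape(10, 10)
    assert np.allclose(normalize_intensity(full), full, atol=1e-9)


def test_normalize_constant_image_warns_and_zeroes():
    with pytest.warns(UserWarning):
        out = normalize_intensity(np.full((4, 4), 9.0))
    assert np.array_equal(out, np.zeros((4, 4)))


# -------------------------------------------------------- mean subtraction


def test_mean_subtraction_scalar_grand_mean():
    s1 = _slice(np.full((4, 4), 100.0))
    s2 = _slice(np.full((4, 4), 200.0))
    mean, centered = compute_mean_and_subtract([s1, s2])
    assert mean == pytest.approx(150.0)
    assert np.allclose(centered[0].image, -50.0)
    assert np.allclose(centered[1].image, +50.0)
    grand = np.concatenate([c.image.ravel() for c in centered]).mean()
    assert grand == pytest.approx(0.0, abs=1e-9)


def test_mean_subtraction_empty_set_raises():
    with pytest.raises(ValueError):
        compute_mean_and_subtract([])


# ------------------------------------------------------------------ shift


def test_shift_identity_and_single_pixel_convention():
    img = np.zeros((8, 8))
    lab = np.zeros((8, 8), dtype=np.uint8)
    img[3, 4] = 1.0
    lab[3, 4] = 1
    s = _slice(img, lab)
    same = augment_shift(s, 0, 0)
    assert np.array_equal(same.image, img) and np.array_equal(same.label, lab)
    moved = augment_shift(s, 1, 0)  # x = column convention
    assert moved.label[3, 5] == 1 and moved.label.sum() == 1
    moved = augment_shift(s, 0, 2)
    assert moved.label[5, 4] == 1


@given(st.integers(-5, 5), st.integers(-5, 5), st.integers(0, 2**16))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_shift_never_grows_foreground(dx, dy, seed):
    rng = np.random.default_rng(seed)
    lab = (rng.random((12, 12)) > 0.6).astype(np.uint8)
    s = _slice(rng.random((12, 12)), lab)
    out = augment_shift(s, dx, dy)
    assert out.label.sum() <= lab.sum()
    assert set(np.unique(out.label)) <= {0, 1}


def test_shift_beyond_image_raises():
    with pytest.raises(ValueError):
        augment_shift(_slice(np.zeros((8, 8))), 8, 0)


# ------------------------------------------------------- deform/intensity


def _disc_slice(n=64, r=16):
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lab = ((rr - n / 2) ** 2 + (cc - n / 2) ** 2 <= r * r).astype(np.uint8)
    return _slice(lab * 200.0, lab)


def test_deform_zero_magnitude_is_identity():
    cfg = AugmentationConfig(deform_alpha_px=0.0, intensity_field_amplitude=0.0)
    s = _disc_slice()
    out = augment_deform_intensity(s, cfg, seed=3)
    assert np.allclose(out.image, s.image)
    assert np.array_equal(out.label, s.label)


def test_deform_label_stays_binary_and_area_stable():
    cfg = AugmentationConfig(deform_grid_sigma_px=8.0, deform_alpha_px=3.0,
                             intensity_field_amplitude=0.1,
                             intensity_field_scale_px=20.0)
    s = _disc_slice()
    area0 = int(s.label.sum())
    for seed in range(5):
        out = augment_deform_intensity(s, cfg, seed=seed)
        assert set(np.unique(out.label)) <= {0, 1}
        assert abs(int(out.label.sum()) - area0) <= 0.15 * area0


def test_deform_deterministic_per_seed():
    cfg = AugmentationConfig()
    s = _disc_slice()
    a = augment_deform_intensity(s, cfg, seed=11)
    b = augment_deform_intensity(s, cfg, seed=11)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.label, b.label)


# ------------------------------------------------------ training-set law


def _toy_cases(n_cases=2, n_slices=5, size=16):
    rng = np.random.default_rng(0)
    cases = []
    for i in range(n_cases):
        vox = rng.uniform(0, 100, size=(n_slices, size, size))
        mask = (rng.random((n_slices, size, size)) > 0.7).astype(np.uint8)
        vol = ImageVolume(vox, (1.0, 1.0), 2.5, case_id=f"t{i}")
        cases.append((vol, mask))
    return cases


@pytest.mark.parametrize("n_slices,variants,expected",
                         [(5, 2, 30), (10, 0, 20), (10, 2, 60)])
def test_training_set_count_law(n_slices, variants, expected):
    cases = _toy_cases(2, n_slices)
    cfg = AugmentationConfig(max_shift_px=2, deform_grid_sigma_px=3.0,
                             deform_alpha_px=1.0, variants_per_slice=variants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # some random slices are constant
        out = build_training_set(cases, cfg)
    assert len(out) == expected


def test_shuffle_is_a_permutation_of_provenance():
    cases = _toy_cases(1, 6)
    cfg = AugmentationConfig(max_shift_px=2, deform_alpha_px=1.0,
                             deform_grid_sigma_px=3.0, variants_per_slice=2,
                             seed=5)
    out = build_training_set(cases, cfg)
    origins = sorted((p[0], p[1]) for p in (s.provenance for s in out))
    assert origins == sorted([("t0", k) for k in range(6)] * 3)


def test_augmented_variants_share_geometry_with_labels():
    """Every augmentation transforms image and label together: a pure
    foreground/background intensity split must survive augmentation."""
    n = 32
    lab = np.zeros((n, n), dtype=np.uint8)
    lab[8:24, 8:24] = 1
    vox = np.where(lab, 200.0, 10.0)[None].repeat(3, axis=0)
    vol = ImageVolume(vox, (1.0, 1.0), 2.5, case_id="geom")
    cfg = AugmentationConfig(max_shift_px=4, deform_grid_sigma_px=6.0,
                             deform_alpha_px=2.0,
                             intensity_field_amplitude=0.05,
                             intensity_field_scale_px=16.0,
                             variants_per_slice=2, seed=1)
    for s in build_training_set([(vol, lab[None].repeat(3, axis=0))], cfg):
        fg = s.image[s.label == 1]
        bg = s.image[s.label == 0]
        if len(fg) and len(bg):
            # interpolation blurs the edge; interior separation must persist
            assert np.median(fg) > np.median(bg)
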