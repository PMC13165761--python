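"""Preprocessing operations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestfusion.data import EnvSeries
from pestfusion.preprocessing import (AugmentationPolicy, UnresolvedGapError,
                                      adjust_brightness, apply_augmentation,
                                      counts_to_density, crop_patches,
                                      flip_image, impute_missing,
                                      interpolate_series, rotate_image,
                                      rotate_point, smooth_counts,
                                      standardize_image, standardize_series,
                                      unstandardize_image)
from pestfusion.synthetic import simulate_trap_counts

rng = np.random.default_rng(77)


# -- brute-force oracles ----------------------------------------------------

def brute_interp(times, values, t):
    i = np.searchsorted(times, t, side="right") - 1
    i = min(max(i, 0), len(times) - 2)
    t0, t1 = times[i], times[i + 1]
    return values[i] + (t - t0) / (t1 - t0) * (values[i + 1] - values[i])


def brute_impute(times, values, mask, delta):
    out = values.copy()
    for i in range(len(times)):
        if not mask[i]:
            sel = [k for k in range(len(times))
                   if mask[k] and abs(times[k] - times[i]) <= delta]
            out[i] = np.mean([values[k] for k in sel])
    return out


def brute_smooth(c, k):
    n = len(c)
    out = np.empty(n, dtype=float)
    for t in range(n):
        lo, hi = max(0, t - k), min(n - 1, t + k)
        out[t] = np.mean(c[lo:hi + 1])
    return out


def _series(values, times=None, mask=None, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T \
        if np.asarray(values).ndim == 1 else np.asarray(values, dtype=float)
    L, D = values.shape
    times = np.arange(L, dtype=float) * 10 if times is None else times
    mask = np.ones((L, D), dtype=bool) if mask is None else mask
    names = tuple(f"v{j}" for j in range(D)) if names is None else names
    return EnvSeries(times, values, mask, names)


# -- image ops --------------------------------------------------------------

def test_crop_patches_counts_and_contents():
    img = np.arange(16, dtype=float).reshape(4, 4)
    patches = crop_patches(img, 2, 2, stride=2)
    assert patches.shape == (4, 2, 2)
    assert np.array_equal(patches[0], img[:2, :2])
    assert np.array_equal(patches[3], img[2:, 2:])
    # identity crop
    assert np.array_equal(crop_patches(img, 4, 4, stride=1)[0], img)
    # corner enumeration oracle on a 5x5 image
    img5 = rng.standard_normal((5, 5))
    got = crop_patches(img5, 2, 2, stride=2)
    corners = [(y, x) for y in range(0, 4, 2) for x in range(0, 4, 2)]
    assert len(got) == len(corners) == 4
    for patch, (y, x) in zip(got, corners):
        assert np.array_equal(patch, img5[y:y + 2, x:x + 2])


def test_crop_patches_closed_form_count():
    img = rng.standard_normal((13, 9, 3))
    for (h, w, s) in [(3, 3, 2), (5, 4, 3), (13, 9, 1)]:
        expected = ((13 - h) // s + 1) * ((9 - w) // s + 1)
        assert len(crop_patches(img, h, w, s)) == expected


def test_crop_window_larger_than_image_raises():
    with pytest.raises(ValueError):
        crop_patches(np.zeros((4, 4)), 5, 2)


def test_standardize_image_cases():
    img = np.full((8, 8), 3.0)
    assert np.all(standardize_image(img, 3.0, 2.0) == 0.0)
    two_point = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert set(np.unique(standardize_image(two_point, 0.5, 0.5))) == {-1.0,
                                                                      1.0}
    x = rng.random((16, 16, 3))
    z = standardize_image(x, x.mean(), x.std())
    assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6
    with pytest.raises(ValueError):
        standardize_image(x, 0.0, 0.0)


def test_standardize_unstandardize_roundtrip():
    x = rng.random((10, 10))
    back = unstandardize_image(standardize_image(x, 0.3, 0.2), 0.3, 0.2)
    assert np.max(np.abs(back - x)) < 1e-10


def test_rotation_matrix_quarter_turn():
    assert np.allclose(rotate_point((1.0, 0.0), np.pi / 2), (0.0, 1.0),
                       atol=1e-12)


def test_rotate_image_identity_and_group_property():
    img = rng.random((9, 9, 3))
    assert np.array_equal(rotate_image(img, 0.0), img)
    out = img
    for _ in range(4):
        out = rotate_image(out, np.pi / 2)
    assert np.array_equal(out, img)


def test_rotate_image_arbitrary_angle_keeps_shape_and_range():
    img = rng.random((16, 16, 3))
    out = rotate_image(img, 0.3)
    assert out.shape == img.shape
    assert out.min() >= img.min() - 1e-9 and out.max() <= img.max() + 1e-9


def test_adjust_brightness_identity_scaling_saturation():
    img = np.full((4, 4), 0.25)
    assert np.array_equal(adjust_brightness(img, 1.0, 0.0), img)
    assert np.allclose(adjust_brightness(img, 2.0, 0.0), 0.5)
    assert np.all(adjust_brightness(rng.random((4, 4)), 1.0, 1.0) == 1.0)
    with pytest.raises(ValueError):
        adjust_brightness(img, 0.0, 0.0)


def test_identity_augmentation_leaves_image_bit_identical():
    policy = AugmentationPolicy(p_rotate=0.0, p_flip_horizontal=0.0,
                                p_flip_vertical=0.0, p_brightness=0.0)
    img = rng.random((12, 12, 3))
    out = apply_augmentation(img, policy, np.random.default_rng(0))
    assert np.array_equal(out, img)


def test_flip_composition_is_involution():
    img = rng.random((6, 8))
    assert np.array_equal(
        flip_image(flip_image(img, horizontal=True), horizontal=True), img)


# -- series ops -------------------------------------------------------------

def test_interpolation_knots_midpoint_and_oracle():
    s = _series(np.array([0.0, 10.0]), times=np.array([0.0, 10.0]))
    out = interpolate_series(s, [4.0])
    assert np.allclose(out.values[0, 0], 4.0)
    # knot identity
    s2 = _series(rng.standard_normal((7, 2)))
    out2 = interpolate_series(s2, s2.times)
    assert np.max(np.abs(out2.values - s2.values)) < 1e-12
    # 100 random targets against the brute-force two-point oracle
    targets = rng.uniform(s2.times[0], s2.times[-1], size=100)
    got = interpolate_series(s2, np.sort(targets))
    for t, row in zip(np.sort(targets), got.values):
        for j in range(2):
            assert abs(row[j] - brute_interp(s2.times, s2.values[:, j], t)) \
                < 1e-12


def test_interpolation_refuses_extrapolation():
    s = _series(rng.standard_normal(5))
    with pytest.raises(ValueError):
        interpolate_series(s, [-1.0])
    with pytest.raises(ValueError):
        interpolate_series(s, [s.times[-1] + 1.0])


def test_imputation_simple_neighborhoods():
    vals = np.array([[2.0], [np.nan], [4.0]])
    mask = np.array([[True], [False], [True]])
    s = _series(vals, times=np.array([0.0, 10.0, 20.0]), mask=mask)
    assert impute_missing(s, delta=10.0).values[1, 0] == pytest.approx(3.0)
    # single neighbor
    vals2 = np.array([[np.nan], [7.0], [np.nan]])
    mask2 = np.array([[False], [True], [False]])
    s2 = _series(vals2, times=np.array([0.0, 10.0, 20.0]), mask=mask2)
    out = impute_missing(s2, delta=10.0)
    assert np.allclose(out.values[:, 0], 7.0)


def test_imputation_matches_bruteforce_oracle():
    for _ in range(20):
        L = 40
        times = np.arange(L, dtype=float) * 10
        vals = rng.standard_normal((L, 3))
        mask = rng.random((L, 3)) > 0.1
        mask[0] = mask[-1] = True  # keep ends anchored
        s = _series(np.where(mask, vals, np.nan), times=times, mask=mask)
        delta = 30.0  # spans 3 steps
        try:
            got = impute_missing(s, delta)
        except UnresolvedGapError:
            continue
        for j in range(3):
            expect = brute_impute(times, vals[:, j], mask[:, j], delta)
            sel = ~mask[:, j]
            assert np.max(np.abs(got.values[sel, j] - expect[sel])) < 1e-12


def test_imputation_empty_neighborhood_raises_with_timestamps():
    vals = np.array([[1.0], [np.nan], [1.0]])
    mask = np.array([[True], [False], [True]])
    s = _series(vals, times=np.array([0.0, 100.0, 200.0]), mask=mask)
    with pytest.raises(UnresolvedGapError) as exc:
        impute_missing(s, delta=10.0)
    assert 100.0 in exc.value.timestamps


def test_standardize_series_recompute_and_zero_variance_error():
    vals = np.column_stack([rng.standard_normal(50) * 5 + 3,
                            rng.standard_normal(50) * 0.1])
    s = _series(vals)
    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    out = standardize_series(s, mu, sd)
    assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(out.values.std(axis=0), 1.0, atol=1e-10)
    with pytest.raises(ValueError, match="v1"):
        standardize_series(s, mu, np.array([1.0, 0.0]))


def test_smoothing_identity_center_and_oracle():
    c = np.array([1.0, 2.0, 3.0])
    assert np.array_equal(smooth_counts(c, 0), c)
    assert smooth_counts(c, 1)[1] == pytest.approx(2.0)
    for _ in range(10):
        c = rng.integers(0, 50, size=50).astype(float)
        got = smooth_counts(c, 2)
        expect = brute_smooth(c, 2)
        assert np.max(np.abs(got - expect)) < 1e-12


@given(st.integers(min_value=0, max_value=5))
@settings(deadline=None, max_examples=20)
def test_smoothing_preserves_constant_series(k):
    c = np.full(20, 7.0)
    assert np.allclose(smooth_counts(c, k), 7.0)


def test_counts_to_density_and_roundtrip():
    assert counts_to_density(0, 50.0) == 0.0
    assert counts_to_density(50, 50.0) == 1.0
    with pytest.raises(ValueError):
        counts_to_density(5, 0.0)
    # Monte-Carlo unbiasedness against the trap simulator
    counts = simulate_trap_counts(0.5, 50.0, 10000, 3)
    est = counts_to_density(counts, 50.0).mean()
    se = np.sqrt(25.0 / 10000) / 50.0
    assert abs(est - 0.5) < 3 * se
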