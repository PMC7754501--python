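"""Scale-space filtering and feature assembly."""

import numpy as np
import pytest

from fibsemseg.features import (
    FeatureMatrix,
    ScaleSpaceConfig,
    assemble_features,
    gaussian_kernel,
    gaussian_scale_space,
    mirror_index,
    slice_features,
)
from fibsemseg.preprocess import ImageVolume


def test_default_config_has_99_features():
    cfg = ScaleSpaceConfig()
    assert len(cfg.sigmas) == 9
    assert len(cfg.slice_offsets) == 11
    assert cfg.n_features == 99
    assert len(cfg.columns()) == 99


def test_filter_widths_are_odd_and_follow_the_size_rule():
    cfg = ScaleSpaceConfig()
    for sigma in cfg.sigmas[1:]:
        hw = cfg.half_width(sigma)
        width = 2 * hw + 1
        assert width % 2 == 1
        if sigma == max(cfg.sigmas):
            assert width == 2 * sigma + 1  # reduced at the largest scale
        else:
            assert width == 4 * sigma + 1


def test_config_rejects_negative_or_unsorted_scales():
    with pytest.raises(ValueError):
        ScaleSpaceConfig(sigmas=(0, -1.0))
    with pytest.raises(ValueError):
        ScaleSpaceConfig(sigmas=(0, 4, 2))


def test_kernels_are_renormalized_to_unit_sum():
    for sigma, hw in [(1, 2), (8, 16), (128, 128)]:
        k = gaussian_kernel(sigma, hw)
        assert k.size == 2 * hw + 1
        assert k.sum() == pytest.approx(1.0, abs=1e-15)


def test_constant_volume_is_fixed_point_of_all_scales():
    vol = ImageVolume(np.full((40, 40, 3), 0.42))
    for f in gaussian_scale_space(vol):
        np.testing.assert_allclose(f, 0.42, atol=1e-12)


def test_impulse_response_equals_truncated_kernel_weight():
    """Unit impulse: the centre value is the centre weight of the normalized
    truncated 5x5 sampled Gaussian at sigma = 1."""
    img = np.zeros((21, 21, 1))
    img[10, 10, 0] = 1.0
    # include a larger scale so sigma=1 keeps the full 4*sigma+1 width
    cfg = ScaleSpaceConfig(sigmas=(0, 1, 2))
    filtered = gaussian_scale_space(img, cfg)[1]
    k = gaussian_kernel(1.0, 2)
    k2d = np.outer(k, k)  # separable 5x5 kernel
    assert filtered[10, 10, 0] == pytest.approx(k2d[2, 2], abs=1e-14)
    np.testing.assert_allclose(filtered[8:13, 8:13, 0], k2d, atol=1e-14)


def test_sigma_zero_returns_input_unchanged(rng):
    data = rng.uniform(size=(16, 16, 2))
    filtered = gaussian_scale_space(data, ScaleSpaceConfig(sigmas=(0, 2)))
    np.testing.assert_array_equal(filtered[0], data)


def test_smoothing_variance_is_nonincreasing_in_sigma(rng):
    data = rng.uniform(size=(64, 64, 1))
    filtered = gaussian_scale_space(data, ScaleSpaceConfig(sigmas=(0, 1, 2, 4, 8)))
    variances = [f.var() for f in filtered]
    assert all(a >= b - 1e-12 for a, b in zip(variances, variances[1:]))


def test_feature_linearity_under_affine_intensity_transform(rng):
    """features(a + b*I) == a + b*features(I) exactly (unit-sum kernels)."""
    data = rng.uniform(0.2, 0.6, size=(24, 24, 11))
    cfg = ScaleSpaceConfig(sigmas=(0, 1, 2, 4))
    pixels = np.column_stack(
        [rng.integers(0, 24, 20), rng.integers(0, 24, 20), rng.integers(0, 11, 20)]
    )
    a, b = 0.07, 0.9
    f_base = assemble_features(gaussian_scale_space(data, cfg), pixels, cfg)
    f_trans = assemble_features(gaussian_scale_space(a + b * data, cfg), pixels, cfg)
    np.testing.assert_allclose(f_trans.values, a + b * f_base.values, atol=1e-12)


def test_shift_equivariance_away_from_boundaries(rng):
    data = rng.uniform(size=(48, 48, 1))
    cfg = ScaleSpaceConfig(sigmas=(0, 2))
    f = gaussian_scale_space(data, cfg)[1]
    f_shift = gaussian_scale_space(np.roll(data, 3, axis=0), cfg)[1]
    np.testing.assert_allclose(f_shift[15:35, 15:35], f[12:32, 15:35], atol=1e-12)


def test_mirror_index_conventions():
    # mirror: slice -1 is slice 1 (edge not repeated)
    assert mirror_index(-1, 10, "mirror") == 1
    assert mirror_index(-3, 10, "mirror") == 3
    assert mirror_index(11, 10, "mirror") == 7
    # reflect: slice -1 is slice 0 (edge repeated)
    assert mirror_index(-1, 10, "reflect") == 0
    assert mirror_index(-3, 10, "reflect") == 2
    assert mirror_index(10, 10, "reflect") == 9


def test_assemble_constant_volume_rows_are_constant():
    cfg = ScaleSpaceConfig()
    filtered = gaussian_scale_space(np.full((12, 12, 12), 0.3), cfg)
    fm = assemble_features(filtered, np.array([[5, 5, 5], [0, 0, 0]]), cfg)
    assert fm.values.shape == (2, 99)
    np.testing.assert_allclose(fm.values, 0.3, atol=1e-12)


def test_assemble_mirror_symmetry_at_z_boundary(rng):
    """At z=0 the mirror convention makes offset -k equal offset +k."""
    cfg = ScaleSpaceConfig(sigmas=(0, 1), slice_offsets=(-2, -1, 0, 1, 2))
    filtered = gaussian_scale_space(rng.uniform(size=(10, 10, 8)), cfg)
    fm = assemble_features(filtered, np.array([[4, 4, 0]]), cfg)
    idx = cfg.column_index()
    for k in (1, 2):
        for sigma in cfg.sigmas:
            assert fm.values[0, idx[(-k, sigma)]] == fm.values[0, idx[(k, sigma)]]


def test_assemble_matches_direct_convolution_oracle(rng):
    """Row values equal an independent per-pixel dense 2D convolution with
    numpy-padded mirror boundaries."""
    data = rng.uniform(size=(14, 15, 6))
    cfg = ScaleSpaceConfig(sigmas=(0, 1, 2), slice_offsets=(-1, 0, 1))
    filtered = gaussian_scale_space(data, cfg)
    pixels = np.array([[0, 0, 0], [7, 8, 3], [13, 14, 5], [2, 11, 1]])
    fm = assemble_features(filtered, pixels, cfg)

    def oracle(x, y, z, off, sigma):
        zi = z + off
        n = data.shape[2]
        while zi < 0 or zi >= n:  # mirror without edge repeat
            zi = -zi if zi < 0 else 2 * (n - 1) - zi
        img = data[:, :, zi]
        if sigma == 0:
            return img[x, y]
        hw = cfg.half_width(sigma)
        k = np.exp(-0.5 * (np.arange(-hw, hw + 1) / sigma) ** 2)
        k /= k.sum()
        k2d = np.outer(k, k)
        padded = np.pad(img, hw, mode="reflect")  # numpy 'reflect' == no edge repeat
        patch = padded[x : x + 2 * hw + 1, y : y + 2 * hw + 1]
        return float((patch * k2d).sum())

    idx = cfg.column_index()
    for r, (x, y, z) in enumerate(pixels):
        for off in cfg.slice_offsets:
            for sigma in cfg.sigmas:
                expected = oracle(x, y, z, off, sigma)
                assert fm.values[r, idx[(off, sigma)]] == pytest.approx(expected, abs=1e-8)


def test_assemble_rejects_out_of_bounds_pixels():
    cfg = ScaleSpaceConfig(sigmas=(0,), slice_offsets=(0,))
    filtered = gaussian_scale_space(np.zeros((5, 5, 5)), cfg)
    with pytest.raises(IndexError):
        assemble_features(filtered, np.array([[5, 0, 0]]), cfg)


def test_slice_features_matches_assemble(rng):
    data = rng.uniform(size=(9, 11, 5))
    cfg = ScaleSpaceConfig(sigmas=(0, 1), slice_offsets=(-1, 0, 1))
    filtered = gaussian_scale_space(data, cfg)
    z = 4  # boundary slice exercises the mirror extension
    xs, ys = np.meshgrid(np.arange(9), np.arange(11), indexing="ij")
    pixels = np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, z)])
    np.testing.assert_allclose(
        slice_features(filtered, z, cfg), assemble_features(filtered, pixels, cfg).values
    )


def test_feature_matrix_validates_column_bijection():
    with pytest.raises(ValueError):
        FeatureMatrix(np.zeros((2, 2)), [(0, 0.0), (0, 0.0)])
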