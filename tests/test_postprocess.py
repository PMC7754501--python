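"""Smooth-threshold regularization, object removal and tuning."""

import numpy as np
import pytest
from scipy import ndimage

from fibsemseg.postprocess import (
    PostprocessConfig,
    apply_postprocess,
    remove_small_objects,
    smooth_threshold,
    tune_postprocess,
)


def test_uniform_scores_threshold_cleanly():
    cfg = PostprocessConfig(sigma_xy=2.796, threshold=0.4495)
    assert (smooth_threshold(np.full((8, 8, 3), 0.6), cfg) == 1).all()
    assert (smooth_threshold(np.full((8, 8, 3), 0.3), cfg) == 0).all()


def test_zero_sigma_single_pass_is_plain_thresholding(rng):
    scores = rng.uniform(size=(10, 10, 4))
    cfg = PostprocessConfig(sigma_xy=0.0, threshold=0.5, passes=1)
    np.testing.assert_array_equal(smooth_threshold(scores, cfg), (scores >= 0.5).astype(np.uint8))


def test_two_pass_matches_sequential_reference(rng):
    """Voxel-exact agreement with an explicitly sequential implementation."""
    scores = rng.uniform(size=(24, 24, 6))
    cfg = PostprocessConfig(sigma_xy=1.7, threshold=0.45, passes=2)
    result = smooth_threshold(scores, cfg)

    ref = np.empty_like(result)
    for z in range(scores.shape[2]):  # reference smooths slice by slice
        s1 = ndimage.gaussian_filter(scores[:, :, z], 1.7, mode="mirror")
        b1 = (s1 >= 0.45).astype(float)
        s2 = ndimage.gaussian_filter(b1, 1.7, mode="mirror")
        ref[:, :, z] = (s2 >= 0.45).astype(np.uint8)
    np.testing.assert_array_equal(result, ref)


def test_no_smoothing_across_slices(rng):
    """A slice's output only depends on that slice's scores."""
    scores = rng.uniform(size=(16, 16, 5))
    cfg = PostprocessConfig(sigma_xy=2.0, threshold=0.5)
    base = smooth_threshold(scores, cfg)
    perturbed = scores.copy()
    perturbed[:, :, 0] = rng.uniform(size=(16, 16))
    out = smooth_threshold(perturbed, cfg)
    np.testing.assert_array_equal(out[:, :, 1:], base[:, :, 1:])


def test_lowering_threshold_never_shrinks_solid(rng):
    scores = rng.uniform(size=(20, 20, 3))
    hi = smooth_threshold(scores, PostprocessConfig(sigma_xy=1.5, threshold=0.6))
    lo = smooth_threshold(scores, PostprocessConfig(sigma_xy=1.5, threshold=0.4))
    assert (lo >= hi).all()


def test_scores_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        smooth_threshold(np.full((4, 4, 2), 1.5))


def test_isolated_voxel_is_flipped():
    mask = np.ones((10, 10, 5), dtype=np.uint8)
    mask[5, 5, 2] = 0  # single pore voxel in solid
    out = remove_small_objects(mask, min_size=100)
    assert out[5, 5, 2] == 1
    assert (out == 1).all()


def test_component_of_exactly_min_size_is_retained():
    mask = np.ones((10, 10, 4), dtype=np.uint8)
    mask[0:5, 0:5, 0:4] = 0  # 100-voxel pore block
    out = remove_small_objects(mask, min_size=100)
    np.testing.assert_array_equal(out, mask)
    out99 = remove_small_objects(mask, min_size=101)
    assert (out99 == 1).all()


def test_removal_matches_flood_fill_oracle(rng):
    """Equality with an independent BFS component labelling on random masks."""

    def bfs_components(binary):
        visited = np.zeros_like(binary, dtype=bool)
        comps = []
        nx, ny, nz = binary.shape
        for start in zip(*np.nonzero(binary & ~visited)):
            if visited[start]:
                continue
            stack, comp = [start], []
            visited[start] = True
            while stack:
                x, y, z = stack.pop()
                comp.append((x, y, z))
                for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    p = (x + dx, y + dy, z + dz)
                    if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz:
                        if binary[p] and not visited[p]:
                            visited[p] = True
                            stack.append(p)
            comps.append(comp)
        return comps

    for trial in range(3):
        mask = (rng.uniform(size=(12, 12, 12)) < 0.45).astype(np.uint8)
        min_size = 9
        expected = mask.copy()
        for phase in (0, 1):
            for comp in bfs_components(expected == phase):
                if len(comp) < min_size:
                    for p in comp:
                        expected[p] = 1 - phase
        out = remove_small_objects(mask, min_size=min_size, connectivity=6)
        np.testing.assert_array_equal(out, expected)


def test_removal_is_idempotent_on_stable_masks():
    mask = np.zeros((12, 12, 6), dtype=np.uint8)
    mask[2:10, 2:10, :] = 1      # large solid block
    mask[4:6, 4:6, 2:4] = 0      # 8-voxel pore, removed
    once = remove_small_objects(mask, min_size=20)
    twice = remove_small_objects(once, min_size=20)
    np.testing.assert_array_equal(once, twice)


def test_removal_2d_connectivity_treats_slices_independently():
    mask = np.ones((8, 8, 3), dtype=np.uint8)
    mask[3, 3, :] = 0  # a 3-voxel pore line along z
    out3d = remove_small_objects(mask, min_size=3, connectivity=6)
    np.testing.assert_array_equal(out3d, mask)  # size 3 in 3D: retained
    out2d = remove_small_objects(mask, min_size=3, connectivity="2d")
    assert (out2d == 1).all()  # per-slice components have size 1: removed


def test_non_binary_mask_rejected():
    with pytest.raises(ValueError):
        remove_small_objects(np.full((4, 4, 2), 2))


def test_tune_recovers_threshold_near_half(rng):
    """Scores built from labels plus small noise: tuning keeps T near 0.5
    and never ends below the starting objective."""
    labels, scores = [], []
    for _ in range(3):
        lab = (ndimage.gaussian_filter(rng.standard_normal((32, 32)), 3) > 0).astype(np.uint8)
        noisy = np.clip(lab + rng.normal(0, 0.15, lab.shape), 0, 1)
        labels.append(lab)
        scores.append(noisy[:, :, None])
    cfg, tuned_miou = tune_postprocess(scores, labels)
    assert 0.3 < cfg.threshold < 0.7
    from fibsemseg.metrics import miou as _miou

    start = PostprocessConfig(sigma_xy=2.0, threshold=0.5)
    start_miou = _miou(
        np.concatenate([l.ravel() for l in labels]),
        np.concatenate([smooth_threshold(s, start).ravel() for s in scores]),
    )
    assert tuned_miou >= start_miou - 1e-12
    # consistency: the returned objective re-evaluates to itself
    re_miou = _miou(
        np.concatenate([l.ravel() for l in labels]),
        np.concatenate([smooth_threshold(s, cfg).ravel() for s in scores]),
    )
    assert tuned_miou == pytest.approx(re_miou, abs=1e-12)


def test_tune_one_iteration_budget_returns_start(rng):
    lab = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
    cfg, _ = tune_postprocess([lab[:, :, None].astype(float)], [lab], maxiter=1)
    assert cfg.sigma_xy == 2.0 and cfg.threshold == 0.5


def test_tune_rejects_constant_labels():
    with pytest.raises(ValueError, match="constant"):
        tune_postprocess([np.zeros((8, 8, 1))], [np.zeros((8, 8), dtype=np.uint8)])


def test_apply_postprocess_combines_both_steps(rng):
    scores = (ndimage.gaussian_filter(rng.uniform(size=(24, 24, 4)), 2) > 0.5).astype(float)
    cfg = PostprocessConfig(sigma_xy=1.0, threshold=0.5, min_object_size=5)
    out = apply_postprocess(scores, cfg)
    assert set(np.unique(out)) <= {0, 1}
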