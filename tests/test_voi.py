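"""Background removal, region growing and tube VOI extraction."""

from collections import deque

import numpy as np
import pytest

from voxreflect import (
    Volume3D,
    default_phantom_spec,
    detect_tubes,
    extract_voi,
    generate_phantom,
    grow_region_3d,
    remove_background,
)
from voxreflect.voi import TubeVOI


def brute_force_max_between_class_variance(values: np.ndarray) -> float:
    """Independent oracle: exhaustive between-class-variance maximization
    over the 256-bin histogram (returns the maximal variance)."""
    flat = values.ravel()
    counts, edges = np.histogram(flat, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best_sigma = -1.0
    for k in range(1, 256):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        best_sigma = max(best_sigma, w0 * w1 * (mu0 - mu1) ** 2)
    return best_sigma


def between_class_variance_of_split(values: np.ndarray, mask: np.ndarray) -> float:
    """Between-class variance achieved by a foreground mask, on the same
    256-bin histogram discretization as the oracle."""
    counts, edges = np.histogram(values.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    # bin-level class assignment induced by the mask's threshold
    thr = values[mask].min()
    hi = centers >= thr
    w0, w1 = counts[~hi].sum(), counts[hi].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[~hi] * centers[~hi]).sum() / w0
    mu1 = (counts[hi] * centers[hi]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def bfs_flood_fill(band: np.ndarray, seed) -> np.ndarray:
    """Independent 26-connected flood-fill oracle."""
    out = np.zeros_like(band)
    if not band[seed]:
        return out
    shape = band.shape
    q = deque([seed])
    out[seed] = True
    while q:
        a, b, c = q.popleft()
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if da == db == dc == 0:
                        continue
                    j = (a + da, b + db, c + dc)
                    if all(0 <= j[i] < shape[i] for i in range(3)):
                        if band[j] and not out[j]:
                            out[j] = True
                            q.append(j)
    return out


class TestRemoveBackground:
    def test_two_level_volume_exact(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2:4] = 100.0
        mask = remove_background(Volume3D(vals, (1, 1, 1)))
        assert np.array_equal(mask, vals == 100.0)

    def test_threshold_maximizes_between_class_variance(self, rng):
        vals = rng.integers(0, 256, size=(12, 12, 12)).astype(float)
        vals[:6] += 300.0  # create real structure
        mask = remove_background(Volume3D(vals, (1, 1, 1)))
        achieved = between_class_variance_of_split(vals, mask)
        best = brute_force_max_between_class_variance(vals)
        assert achieved == pytest.approx(best, rel=1e-9)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="single intensity"):
            remove_background(Volume3D(np.full((4, 4, 4), 5.0), (1, 1, 1)))


class TestGrowRegion:
    def test_uniform_cube_recovered_exactly(self):
        vals = np.zeros((10, 10, 10))
        vals[2:6, 2:6, 2:6] = 100.0
        mask = grow_region_3d(Volume3D(vals, (1, 1, 1)), (3, 3, 3), 50.0, 150.0)
        assert np.array_equal(mask, vals == 100.0)

    def test_matches_bfs_flood_fill_oracle(self, rng):
        vals = rng.uniform(0, 1, (10, 10, 10))
        band = (vals >= 0.4) & (vals <= 0.9)
        seed = tuple(np.argwhere(band)[0])
        mask = grow_region_3d(Volume3D(vals, (1, 1, 1)), seed, 0.4, 0.9)
        assert np.array_equal(mask, bfs_flood_fill(band, seed))

    def test_only_seeded_component_returned(self):
        vals = np.zeros((12, 12, 12))
        vals[1:4, 1:4, 1:4] = 100.0
        vals[8:11, 8:11, 8:11] = 100.0
        mask = grow_region_3d(Volume3D(vals, (1, 1, 1)), (2, 2, 2), 50.0, 150.0)
        assert mask[1:4, 1:4, 1:4].all() and not mask[8:11, 8:11, 8:11].any()

    def test_seed_outside_band_rejected_naming_value(self):
        vol = Volume3D(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="0.0"):
            grow_region_3d(vol, (1, 1, 1), 10.0, 20.0)

    def test_invariant_to_seed_within_component(self, rng):
        vals = rng.uniform(0, 1, (9, 9, 9))
        band = vals >= 0.5
        vol = Volume3D(vals, (1, 1, 1))
        seeds = [tuple(s) for s in np.argwhere(band)[:5]]
        first = grow_region_3d(vol, seeds[0], 0.5, np.inf)
        for s in seeds[1:]:
            if first[s]:
                assert np.array_equal(grow_region_3d(vol, s, 0.5, np.inf), first)


class TestDetectTubes:
    def test_three_tube_phantom_centroids_and_counts(self):
        spec = default_phantom_spec(noise_sigma=0.0)
        vol, labels, _ = generate_phantom(spec)
        vois = detect_tubes(vol, roles=["test", "control", "water"])
        assert len(vois) == 3
        analytic = np.pi * 4.0**2 * 20.0 / np.prod(spec.spacing_mm)
        for voi, tube in zip(vois, spec.tubes):
            np.testing.assert_allclose(
                voi.centroid_mm, tube.center_mm, atol=max(spec.spacing_mm)
            )
            assert abs(voi.voxel_count - analytic) / analytic < 0.05
        # masks pairwise disjoint
        total = sum(v.mask.astype(int) for v in vois)
        assert total.max() == 1

    def test_noiseless_chain_reproduces_label_mask_exactly(self):
        spec = default_phantom_spec(noise_sigma=0.0)
        vol, labels, _ = generate_phantom(spec)
        vois = detect_tubes(vol)
        combined = np.zeros(vol.shape, dtype=int)
        for i, v in enumerate(vois):
            combined[v.mask] = i + 1
        assert np.array_equal(combined > 0, labels > 0)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            detect_tubes(Volume3D(np.full((8, 8, 8), 3.0), (1, 1, 1)))

    def test_size_window_filters_components(self):
        vals = np.zeros((16, 16, 16))
        vals[1:3, 1:3, 1:3] = 100.0  # 8 voxels
        vals[8:14, 8:14, 8:14] = 100.0  # 216 voxels
        vol = Volume3D(vals, (1, 1, 1))
        vois = detect_tubes(vol, min_voxels=50, max_voxels=1000)
        assert len(vois) == 1 and vois[0].voxel_count == 216

    def test_role_assignment_from_seed_points(self):
        spec = default_phantom_spec(noise_sigma=0.0)
        vol, labels, _ = generate_phantom(spec)
        seed = tuple(np.argwhere(labels == 3)[0])
        vois = detect_tubes(vol, roles={"water": seed})
        assert [v.role for v in vois].count("water") == 1
        water = [v for v in vois if v.role == "water"][0]
        assert water.mask[seed]


class TestExtractVoi:
    def _tube_volume(self):
        spec = default_phantom_spec(noise_sigma=0.0)
        vol, labels, _ = generate_phantom(spec)
        voi = TubeVOI.from_mask(labels == 1, vol, role="test")
        return vol, voi

    def test_padded_crop_is_bbox_plus_pad_and_centered(self):
        vol, voi = self._tube_volume()
        sub, submask = extract_voi(vol, voi, pad_voxels=4)
        bbox_size = np.array([b[1] - b[0] + 1 for b in voi.bbox])
        assert sub.shape == tuple(bbox_size + 8)
        center_idx = (np.array(sub.shape) - 1) / 2
        centroid_idx = sub.physical_to_index(voi.centroid_mm)
        np.testing.assert_allclose(centroid_idx, center_idx, atol=0.5)

    def test_zero_pad_crop_equals_bbox(self):
        vol, voi = self._tube_volume()
        sub, submask = extract_voi(vol, voi, pad_voxels=0)
        assert sub.shape == tuple(b[1] - b[0] + 1 for b in voi.bbox)
        assert submask.sum() == voi.voxel_count

    def test_physical_coordinates_preserved(self):
        vol, voi = self._tube_volume()
        sub, _ = extract_voi(vol, voi, pad_voxels=2)
        lo = np.array(sub.meta["voi_offset_voxels"])
        np.testing.assert_allclose(
            sub.index_to_physical([0, 0, 0]), vol.index_to_physical(lo), atol=1e-12
        )
        np.testing.assert_allclose(
            sub.index_to_physical([1, 2, 3]), vol.index_to_physical(lo + [1, 2, 3]), atol=1e-12
        )

    def test_border_clipping_recorded(self):
        vol, voi = self._tube_volume()
        sub, _ = extract_voi(vol, voi, pad_voxels=1000)
        assert sub.meta["voi_clipped"] is True
        assert sub.shape == vol.shape
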