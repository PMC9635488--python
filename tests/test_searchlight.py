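import numpy as np
import pytest
from scipy.stats import t as t_dist

from readrsa.errors import DegenerateDataError
from readrsa.rdm import RDM, compute_rdm
from readrsa.searchlight import (BetaSeries, GroupInferenceConfig,
                                 SearchlightConfig, SearchlightMap,
                                 VolumeGrid, cluster_table, fisher_z,
                                 group_inference, label_clusters, neural_rdm,
                                 read_beta_series, read_volume,
                                 searchlight_map, searchlight_map_slow,
                                 searchlight_maps, smooth_map, sphere_offsets,
                                 write_beta_series, write_volume)


def slabels(n):
    return [f"s{i}" for i in range(n)]


def make_betas(rng, shape=(6, 6, 6), n_stim=10, mask=None, subject="sub00"):
    grid = VolumeGrid(shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    data = rng.normal(size=(n_stim, int(mask.sum())))
    return BetaSeries(subject, grid, slabels(n_stim), mask, data)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_counts(self, radius, count):
        assert len(sphere_offsets(radius)) == count

    @pytest.mark.parametrize("radius", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_enumeration(self, radius):
        expected = {(i, j, k)
                    for i in range(-radius, radius + 1)
                    for j in range(-radius, radius + 1)
                    for k in range(-radius, radius + 1)
                    if i * i + j * j + k * k <= radius * radius}
        got = {tuple(v) for v in sphere_offsets(radius)}
        assert got == expected

    def test_includes_center(self):
        assert (sphere_offsets(2) == 0).all(axis=1).any()


class TestNeuralRdm:
    def test_single_voxel_sphere_rejected(self, rng):
        betas = make_betas(rng)
        with pytest.raises(DegenerateDataError):
            neural_rdm(betas, (0, 0, 0), sphere_offsets(0))

    def test_identical_patterns_distance_zero(self, rng):
        betas = make_betas(rng, n_stim=4)
        betas.data[1] = betas.data[0]
        rdm = neural_rdm(betas, (3, 3, 3), sphere_offsets(1))
        assert rdm.values[0, 1] == pytest.approx(0, abs=1e-12)

    def test_delegates_to_compute_rdm(self, rng):
        betas = make_betas(rng, shape=(7, 7, 7), n_stim=10)
        offsets = sphere_offsets(3)
        rdm = neural_rdm(betas, (3, 3, 3), offsets)
        cols = []
        colmap = -np.ones(343, dtype=int)
        colmap[np.flatnonzero(betas.mask.ravel())] = np.arange(343)
        for off in offsets:
            c = np.array([3, 3, 3]) + off
            cols.append(np.ravel_multi_index(tuple(c), (7, 7, 7)))
        expected = compute_rdm(betas.data[:, colmap[cols]], betas.labels)
        np.testing.assert_allclose(rdm.values, expected.values, atol=1e-12)


class TestSearchlightMap:
    def test_self_model_gives_one_at_full_occupancy_center(self, rng):
        # mask exactly one radius-1 sphere; with min_occupancy 1.0 only its
        # center qualifies, and the model RDM is that sphere's own RDM
        shape = (5, 5, 5)
        mask = np.zeros(shape, bool)
        for off in sphere_offsets(1):
            mask[tuple(np.array([2, 2, 2]) + off)] = True
        betas = make_betas(rng, shape, n_stim=8, mask=mask)
        model = neural_rdm(betas, (2, 2, 2), sphere_offsets(1),
                           min_occupancy=1.0)
        cfg = SearchlightConfig(radius=1, min_occupancy=1.0)
        out = searchlight_map(betas, model, cfg)
        assert out.values[2, 2, 2] == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(out.values[2, 2, 1]) or out.values[2, 2, 1] != 1.0

    def test_pure_noise_mean_near_zero(self, rng):
        betas = make_betas(rng, shape=(8, 8, 8), n_stim=12)
        model = compute_rdm(rng.normal(size=(12, 9)), slabels(12))
        out = searchlight_map(betas, model, SearchlightConfig(radius=1))
        vals = out.values[np.isfinite(out.values)]
        assert len(vals) >= 50
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 0.02

    def test_matches_per_voxel_loop_oracle(self, rng):
        betas = make_betas(rng, shape=(6, 6, 6), n_stim=9)
        model = compute_rdm(rng.normal(size=(9, 7)), slabels(9))
        control = compute_rdm(rng.normal(size=(9, 7)), slabels(9))
        cfg = SearchlightConfig(radius=2, min_occupancy=0.4)
        fast = searchlight_maps(betas, [("p", model, None),
                                        ("pc", model, control)], cfg)
        slow = searchlight_map_slow(betas, model, cfg)
        np.testing.assert_array_equal(np.isnan(fast["p"].values),
                                      np.isnan(slow.values))
        np.testing.assert_allclose(fast["p"].values, slow.values,
                                   atol=1e-12, equal_nan=True)
        cfg_part = SearchlightConfig(radius=2, min_occupancy=0.4,
                                     method="partial_spearman")
        slow_part = searchlight_map_slow(betas, model, cfg_part, control)
        np.testing.assert_allclose(fast["pc"].values, slow_part.values,
                                   atol=1e-12, equal_nan=True)

    def test_stimulus_order_invariance(self, rng):
        betas = make_betas(rng, shape=(5, 5, 5), n_stim=8)
        model = compute_rdm(rng.normal(size=(8, 6)), slabels(8))
        out1 = searchlight_map(betas, model, SearchlightConfig(radius=1))
        perm = rng.permutation(8)
        betas2 = BetaSeries("sub00", betas.grid,
                            [betas.labels[i] for i in perm], betas.mask,
                            betas.data[perm])
        model2 = RDM([model.labels[i] for i in perm],
                     model.values[np.ix_(perm, perm)])
        out2 = searchlight_map(betas2, model2, SearchlightConfig(radius=1))
        np.testing.assert_allclose(out1.values, out2.values,
                                   atol=1e-12, equal_nan=True)

    def test_partial_requires_control(self, rng):
        betas = make_betas(rng)
        model = compute_rdm(rng.normal(size=(10, 6)), slabels(10))
        with pytest.raises(ValueError, match="control"):
            searchlight_map(betas, model,
                            SearchlightConfig(method="partial_spearman"))


class TestSmoothMap:
    def test_zero_fwhm_identity(self, rng):
        grid = VolumeGrid((6, 6, 6))
        vol = rng.normal(size=(6, 6, 6))
        np.testing.assert_array_equal(smooth_map(vol, 0.0, grid), vol)

    def test_constant_map_unchanged(self):
        grid = VolumeGrid((10, 10, 10))
        vol = np.full((10, 10, 10), 0.7)
        out = smooth_map(vol, 6.0, grid)
        np.testing.assert_allclose(out, 0.7, atol=1e-10)

    def test_constant_map_unchanged_under_mask(self):
        grid = VolumeGrid((10, 10, 10))
        vol = np.full((10, 10, 10), 0.7)
        mask = np.zeros((10, 10, 10), bool)
        mask[3:7, 3:7, 3:7] = True
        out = smooth_map(vol, 6.0, grid, mask)
        np.testing.assert_allclose(out[mask], 0.7, atol=1e-10)
        assert np.isnan(out[~mask]).all()

    def test_impulse_response_fwhm(self):
        # measured FWHM of the response to an impulse within 5% of requested
        grid = VolumeGrid((41, 41, 41), voxel_size=(3.0, 3.0, 3.0))
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        fwhm = 9.0
        out = smooth_map(vol, fwhm, grid)
        profile = out[:, 20, 20]
        half = profile.max() / 2
        x = (np.arange(41) - 20) * 3.0
        above = x[profile >= half]
        measured = above.max() - above.min()
        # sub-voxel: interpolate the crossing
        lo = np.interp(half, profile[:21], x[:21])
        hi = np.interp(half, profile[20:][::-1], x[20:][::-1])
        measured = hi - lo
        assert abs(measured - fwhm) / fwhm < 0.05


class TestGroupInference:
    def make_maps(self, values_list, shape=(4, 4, 4)):
        grid = VolumeGrid(shape)
        return [SearchlightMap(f"s{i}", grid, v, "spearman")
                for i, v in enumerate(values_list)]

    def test_identical_maps_zero_variance_excluded(self, rng):
        shape = (4, 4, 4)
        vol = np.full(shape, 0.3)
        maps = self.make_maps([vol.copy() for _ in range(5)])
        mask = np.ones(shape, bool)
        gmap, table = group_inference(maps, mask,
                                      GroupInferenceConfig(fwhm_mm=0.0))
        assert np.isnan(gmap.t).all()
        assert table.clusters.empty

    def test_t_matches_closed_form(self, rng):
        shape = (3, 3, 3)
        rhos = rng.normal(0.3, 0.1, size=18)
        maps = self.make_maps([np.full(shape, r) for r in rhos], shape)
        mask = np.ones(shape, bool)
        gmap, _ = group_inference(
            maps, mask, GroupInferenceConfig(fwhm_mm=0.0,
                                             cluster_extent_mm3=0.0))
        z = np.arctanh(rhos)
        expected = z.mean() / (z.std(ddof=1) / np.sqrt(18))
        assert gmap.t[1, 1, 1] == pytest.approx(expected, abs=1e-10)
        assert gmap.df == 17

    def test_cluster_extent_threshold(self, rng):
        # two components of 5 and 2 voxels (27 mm^3 voxels) at extent
        # 135 mm^3 -> only the 5-voxel component survives
        shape = (4, 4, 4)
        base = rng.normal(0.0, 0.01, size=(12,) + shape)
        big = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (2, 1, 0)]
        small = [(3, 3, 3), (3, 3, 2)]
        for vox in big + small:
            base[(slice(None),) + vox] += 0.9
        maps = self.make_maps(list(base), shape)
        mask = np.ones(shape, bool)
        cfg = GroupInferenceConfig(fwhm_mm=0.0, cluster_extent_mm3=135.0)
        _, table = group_inference(maps, mask, cfg)
        assert len(table.clusters) == 1
        assert table.clusters.iloc[0]["n_voxels"] == 5
        assert table.clusters.iloc[0]["volume_mm3"] == pytest.approx(135.0)

    def test_needs_two_subjects(self, rng):
        maps = self.make_maps([np.zeros((4, 4, 4))])
        with pytest.raises(ValueError):
            group_inference(maps, np.ones((4, 4, 4), bool))


def _floodfill_oracle(binary, connectivity):
    """Brute-force component labelling by flood fill."""
    offsets = [tuple(o) for o in sphere_offsets(1)] if connectivity == 1 else None
    if connectivity == 2:
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0) and abs(i) + abs(j) + abs(k) <= 2]
    else:
        offsets = [o for o in offsets if o != (0, 0, 0)]
    labels = np.zeros(binary.shape, int)
    current = 0
    for start in np.argwhere(binary):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(np.array(p) + off)
                if all(0 <= q[d] < binary.shape[d] for d in range(3)):
                    if binary[q] and not labels[q]:
                        labels[q] = current
                        stack.append(q)
    return labels, current


@pytest.mark.parametrize("connectivity", [1, 2])
def test_cluster_labels_match_floodfill_oracle(rng, connectivity):
    for _ in range(10):
        binary = rng.random((7, 7, 7)) < 0.25
        labels, n = label_clusters(binary, connectivity)
        olabels, on = _floodfill_oracle(binary, connectivity)
        assert n == on
        # label identities may differ; compare the partition
        got = {}
        for lab in range(1, n + 1):
            got[frozenset(map(tuple, np.argwhere(labels == lab)))] = 1
        expected = {}
        for lab in range(1, on + 1):
            expected[frozenset(map(tuple, np.argwhere(olabels == lab)))] = 1
        assert got.keys() == expected.keys()


class TestFisherZ:
    def test_matches_atanh(self):
        x = np.array([-0.5, 0.0, 0.9])
        np.testing.assert_allclose(fisher_z(x), np.arctanh(x))

    def test_clips_extremes(self):
        assert np.isfinite(fisher_z(np.array([1.0, -1.0]))).all()


class TestNiftiIo:
    def test_beta_series_round_trip(self, rng, tmp_path):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        betas = make_betas(rng, (5, 5, 5), n_stim=4, mask=mask)
        nii, tsv = tmp_path / "b.nii.gz", tmp_path / "b.tsv"
        write_beta_series(betas, nii, tsv)
        back = read_beta_series(nii, tsv, mask, "sub00")
        assert back.labels == betas.labels
        np.testing.assert_allclose(back.data, betas.data, atol=1e-6)
        assert back.grid == betas.grid

    def test_sidecar_length_mismatch_rejected(self, rng, tmp_path):
        betas = make_betas(rng, (4, 4, 4), n_stim=3)
        nii, tsv = tmp_path / "b.nii.gz", tmp_path / "b.tsv"
        write_beta_series(betas, nii, tsv)
        with open(tsv, "a") as fh:
            fh.write("extra\n")
        with pytest.raises(ValueError, match="sidecar"):
            read_beta_series(nii, tsv, betas.mask)

    def test_mask_grid_mismatch_rejected(self, rng, tmp_path):
        betas = make_betas(rng, (4, 4, 4), n_stim=3)
        nii, tsv = tmp_path / "b.nii.gz", tmp_path / "b.tsv"
        write_beta_series(betas, nii, tsv)
        with pytest.raises(ValueError, match="mask shape"):
            read_beta_series(nii, tsv, np.ones((5, 5, 5), bool))

    def test_volume_round_trip(self, rng, tmp_path):
        grid = VolumeGrid((4, 5, 6), voxel_size=(3.0, 3.0, 3.0),
                          origin=(-6.0, 0.0, 3.0))
        vol = rng.normal(size=(4, 5, 6)).astype(np.float32)
        write_volume(vol, grid, tmp_path / "v.nii.gz")
        back, bgrid = read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_allclose(back, vol, atol=1e-6)
        assert bgrid == grid
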