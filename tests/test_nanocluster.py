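import numpy as np
import pytest
from scipy import ndimage

from synaptomo import nanocluster as nc
from synaptomo.volume import VoxelVolume


def ball_mask(shape, center, radius):
    g = np.ogrid[tuple(slice(0, s) for s in shape)]
    return sum((gi - ci) ** 2 for gi, ci in zip(g, center)) <= radius ** 2


class TestThresholdProtein:
    def test_gaussian_tail_fraction(self, rng):
        region = VoxelVolume(np.ones((40, 40, 40), bool), 1.0)
        vol = VoxelVolume(rng.standard_normal((40, 40, 40)), 1.0)
        mask = nc.threshold_protein(vol, region, k=1.5)
        frac = mask.data.mean()
        # upper tail beyond 1.5 SD of a normal is 6.68%
        assert frac == pytest.approx(0.0668, abs=0.005)

    def test_huge_k_selects_nothing(self, rng):
        region = VoxelVolume(np.ones((10, 10, 10), bool), 1.0)
        vol = VoxelVolume(rng.standard_normal((10, 10, 10)), 1.0)
        assert not nc.threshold_protein(vol, region, k=50.0).data.any()

    def test_single_spike_selected(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 10.0
        region = VoxelVolume(np.ones((8, 8, 8), bool), 1.0)
        mask = nc.threshold_protein(VoxelVolume(data, 1.0), region)
        assert mask.data.sum() == 1 and mask.data[4, 4, 4]

    def test_constant_region_rejected(self):
        region = VoxelVolume(np.ones((6, 6, 6), bool), 1.0)
        with pytest.raises(ValueError):
            nc.threshold_protein(VoxelVolume(np.ones((6, 6, 6)), 1.0), region)


class TestLocalDensity:
    def test_full_protein_region_is_100_everywhere(self):
        """Boundary correction: density is 100 even at region edges."""
        region = VoxelVolume(np.zeros((20, 20, 20), bool), 1.0)
        region.data[4:16, 4:16, 4:16] = True
        dens = nc.local_density(region, region, window_voxels=7)
        assert np.allclose(dens.in_region_values, 100.0, atol=1e-6)

    def test_empty_protein_gives_zero(self):
        region = VoxelVolume(np.ones((15, 15, 15), bool), 1.0)
        empty = VoxelVolume(np.zeros((15, 15, 15), bool), 1.0)
        dens = nc.local_density(empty, region, window_voxels=7)
        assert np.allclose(dens.in_region_values, 0.0, atol=1e-6)

    def test_matches_brute_force_window_counts(self, rng):
        shape = (9, 9, 9)
        region = VoxelVolume(rng.random(shape) < 0.7, 1.0)
        region.data[4, 4, 4] = True
        protein = VoxelVolume(region.data & (rng.random(shape) < 0.4), 1.0)
        w = 5
        dens = nc.local_density(protein, region, window_voxels=w)
        kernel = ball_mask((w, w, w), (2, 2, 2), 2.0)
        offsets = np.argwhere(kernel) - 2
        for idx in np.argwhere(region.data):
            neigh = idx + offsets
            ok = np.all((neigh >= 0) & (neigh < 9), axis=1)
            neigh = neigh[ok]
            reg = region.data[tuple(neigh.T)]
            prot = protein.data[tuple(neigh.T)]
            expect = 100.0 * prot[reg].sum() / reg.sum()
            assert dens.volume.data[tuple(idx)] == pytest.approx(expect,
                                                                 abs=1e-6)

    def test_even_window_and_oversized_window_rejected(self):
        region = VoxelVolume(np.ones((10, 10, 10), bool), 1.0)
        with pytest.raises(ValueError):
            nc.local_density(region, region, window_voxels=8)
        with pytest.raises(ValueError):
            nc.local_density(region, region, window_voxels=21)


def _blob_density(shape, centers, sigma=4.0, amp=60.0):
    data = np.zeros(shape)
    g = np.ogrid[tuple(slice(0, s) for s in shape)]
    for c in centers:
        data += amp * np.exp(-sum((gi - ci) ** 2 for gi, ci in zip(g, c))
                             / (2 * sigma ** 2))
    region = VoxelVolume(np.ones(shape, bool), 1.0)
    return nc.LocalDensityMap(VoxelVolume(data, 1.0), region, 9)


class TestDetectSeeds:
    def test_single_blob_single_seed_containing_peak(self):
        dens = _blob_density((24, 24, 24), [(12, 12, 12)])
        seeds, n = nc.detect_seeds(dens)
        assert n == 1
        assert seeds.data[12, 12, 12] > 0

    def test_uniform_density_no_seeds(self):
        region = VoxelVolume(np.ones((12, 12, 12), bool), 1.0)
        dens = nc.LocalDensityMap(VoxelVolume(np.full((12, 12, 12), 40.0),
                                              1.0), region, 9)
        _, n = nc.detect_seeds(dens)
        assert n == 0

    def test_two_separated_blobs_two_seeds(self):
        dens = _blob_density((40, 24, 24), [(10, 12, 12), (30, 12, 12)])
        seeds, n = nc.detect_seeds(dens)
        assert n == 2
        assert seeds.data[10, 12, 12] != seeds.data[30, 12, 12]

    def test_seed_count_monotone_in_factor(self, rng):
        dens = _blob_density((40, 24, 24), [(10, 12, 12), (30, 12, 12)])
        dens.volume.data[dens.region.data] += rng.random(
            int(dens.region.data.sum()))
        counts = [nc.detect_seeds(dens, factor=f)[1]
                  for f in (1.5, 2.0, 2.5, 3.0, 4.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSegmentClusters:
    def test_single_seed_grows_connected_cluster(self):
        dens = _blob_density((24, 24, 24), [(12, 12, 12)])
        seeds, _ = nc.detect_seeds(dens)
        out = nc.segment_clusters(dens, seeds,
                                  nc.SegmentationParams(min_cluster_fraction=0))
        assert out.count == 1
        lab = out.label_volume.data
        n_comp = ndimage.label(lab > 0, np.ones((3, 3, 3)))[1]
        assert n_comp == 1
        assert lab[12, 12, 12] > 0

    def test_two_blobs_split_at_valley_plane(self):
        dens = _blob_density((48, 24, 24), [(14, 12, 12), (34, 12, 12)])
        seeds, n = nc.detect_seeds(dens)
        assert n == 2
        out = nc.segment_clusters(dens, seeds,
                                  nc.SegmentationParams(min_cluster_fraction=0))
        assert out.count == 2
        lab = out.label_volume.data
        # by symmetry the boundary must sit within 1 voxel of the valley
        za = np.argwhere(lab == lab[14, 12, 12])[:, 0]
        zb = np.argwhere(lab == lab[34, 12, 12])[:, 0]
        assert za.max() <= 24 + 1 and zb.min() >= 24 - 1

    def test_all_cluster_voxels_inside_region(self):
        shape = (30, 30, 30)
        region = VoxelVolume(ball_mask(shape, (15, 15, 15), 12), 1.0)
        data = np.zeros(shape)
        g = np.ogrid[:30, :30, :30]
        data += 80 * np.exp(-sum((gi - 15) ** 2 for gi in g) / (2 * 16.0))
        dens = nc.LocalDensityMap(
            VoxelVolume(np.where(region.data, data, np.nan), 1.0), region, 9)
        seeds, _ = nc.detect_seeds(dens)
        out = nc.segment_clusters(dens, seeds)
        assert not (out.label_volume.data[~region.data] > 0).any()


class TestClusterProperties:
    def test_volume_arithmetic(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels.flat[:1000] = 1
        out = nc.cluster_properties(VoxelVolume(labels, 1.36))
        assert out.clusters[0].volume_nm3 == pytest.approx(1000 * 1.36 ** 3)

    def test_symmetric_cluster_com_at_center(self):
        labels = np.zeros((21, 21, 21), dtype=np.int32)
        labels[ball_mask((21, 21, 21), (10, 10, 10), 6)] = 1
        out = nc.cluster_properties(VoxelVolume(labels, 2.0))
        assert np.allclose(out.clusters[0].center_of_mass, 21.0)

    def test_com_matches_brute_force(self, rng):
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        blob = rng.random((12, 12, 12)) < 0.1
        labels[blob] = 1
        out = nc.cluster_properties(VoxelVolume(labels, 1.36))
        oracle = (np.argwhere(blob).mean(axis=0) + 0.5) * 1.36
        assert np.allclose(out.clusters[0].center_of_mass, oracle)


def test_full_pipeline_recovers_planted_clusters():
    """K planted blobs at SNR 3 recovered with correct count and COM."""
    from scipy.spatial import cKDTree

    from synaptomo.synth import SynthParams, generate_density_volume, \
        generate_synapse
    from synaptomo.ultra import define_regions

    p = SynthParams(contact_radius=150.0, vesicle_count=0, n_proximal=0,
                    n_az_clusters=4, n_psd_clusters=1, rng_seed=2,
                    voxel_size=2.72, noise_sd=1 / 3)
    geom = generate_synapse(p)
    vol = generate_density_volume(geom, p.noise_sd, seed=11)
    az_region, _ = define_regions(geom)
    found = nc.detect_nanoclusters(vol, az_region, "AZ", window_voxels=11)
    assert found.count == 4
    d, _ = cKDTree(found.centers()).query(geom.ground_truth.az_cluster_centers)
    assert d.max() < 14.3
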