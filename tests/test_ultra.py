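import numpy as np
import pytest

from synaptomo import ultra
from synaptomo.geometry import SynapseGeometry, Vesicle
from synaptomo.volume import VoxelVolume


def brute_force_distance(mask, voxel_size):
    """Exhaustive all-pairs minimum distance oracle."""
    pts = np.argwhere(mask) * voxel_size
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.array(idx) * voxel_size
        out[idx] = np.min(np.linalg.norm(pts - p, axis=1))
    return out


def _parallel_plane_masks(nz=40, ny=12, nx=12, z_post=5, gap_vox=24,
                          voxel_size=1.0):
    post = np.zeros((nz, ny, nx), dtype=bool)
    pre = np.zeros((nz, ny, nx), dtype=bool)
    post[z_post] = True
    pre[z_post + gap_vox] = True
    return (VoxelVolume(pre, voxel_size), VoxelVolume(post, voxel_size))


class TestDistanceField:
    def test_zero_on_mask_and_simple_value(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[0, 0, 0] = True
        field = ultra.distance_field(VoxelVolume(m, 1.0))
        assert field.data[0, 0, 0] == 0.0
        assert field.data[3, 0, 0] == pytest.approx(3.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(3):
            m = rng.random((10, 10, 10)) < 0.05
            if not m.any():
                m[0, 0, 0] = True
            vol = VoxelVolume(m, 1.36)
            field = ultra.distance_field(vol)
            oracle = brute_force_distance(m, 1.36)
            assert np.allclose(field.data, oracle, atol=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            ultra.distance_field(VoxelVolume(np.zeros((4, 4, 4), bool), 1.0))


class TestMembraneClassification:
    def test_parallel_planes_24nm_all_az(self):
        pre, post = _parallel_plane_masks(gap_vox=24)
        az, psd = ultra.classify_synaptic_membranes(pre, post)
        assert np.array_equal(az.data, pre.data)
        assert np.array_equal(psd.data, post.data)

    @pytest.mark.parametrize("gap", [5, 50])
    def test_out_of_range_planes_empty_with_warning(self, gap):
        pre, post = _parallel_plane_masks(nz=60, gap_vox=gap)
        with pytest.warns(UserWarning):
            az, psd = ultra.classify_synaptic_membranes(pre, post)
        assert not az.data.any() and not psd.data.any()

    def test_bounds_are_strict(self):
        # exactly 10 nm separation is excluded by the open interval
        pre, post = _parallel_plane_masks(nz=30, gap_vox=10)
        with pytest.warns(UserWarning):
            az, _ = ultra.classify_synaptic_membranes(pre, post)
        assert not az.data.any()

    def test_swap_symmetry(self, small_synapse):
        _, geom = small_synapse
        az, psd = ultra.classify_synaptic_membranes(geom.pre_membrane_mask,
                                                    geom.post_membrane_mask)
        psd2, az2 = ultra.classify_synaptic_membranes(geom.post_membrane_mask,
                                                      geom.pre_membrane_mask)
        assert np.array_equal(az.data, az2.data)
        assert np.array_equal(psd.data, psd2.data)


class TestCleftWidth:
    def test_parallel_planes(self):
        pre, post = _parallel_plane_masks(gap_vox=24)
        az, psd = ultra.classify_synaptic_membranes(pre, post)
        assert ultra.cleft_width(az, psd) == pytest.approx(24.0, abs=1.0)

    def test_synthetic_default_cleft_width(self, small_synapse):
        """The generator's study-default cleft comes back at 24.4 +- 1.4."""
        _, geom = small_synapse
        az, psd = ultra.classify_synaptic_membranes(geom.pre_membrane_mask,
                                                    geom.post_membrane_mask)
        assert ultra.cleft_width(az, psd) == pytest.approx(24.4, abs=1.4)

    def test_rotation_invariance(self):
        pre, post = _parallel_plane_masks(nz=40, ny=40, nx=12, gap_vox=20)
        az, psd = ultra.classify_synaptic_membranes(pre, post)
        w0 = ultra.cleft_width(az, psd)
        rot = lambda v: VoxelVolume(np.rot90(v.data, axes=(0, 1)).copy(),
                                    v.voxel_size)
        w90 = ultra.cleft_width(rot(az), rot(psd))
        assert abs(w0 - w90) <= 1.0


class TestRegions:
    def test_band_thickness_100nm(self, small_synapse):
        _, geom = small_synapse
        az_reg, psd_reg = ultra.define_regions(geom)
        vx = geom.voxel_size
        for reg in (az_reg, psd_reg):
            z = np.argwhere(reg.data)[:, 0]
            thickness = (z.max() - z.min() + 1) * vx
            assert abs(thickness - 100.0) <= 4 * vx

    def test_no_vesicles_equals_raw_band(self):
        from synaptomo.synth import SynthParams, generate_synapse
        p = SynthParams(contact_radius=80, vesicle_count=0, n_proximal=0,
                        n_az_clusters=1, n_psd_clusters=1, rng_seed=5)
        g0 = generate_synapse(p)
        az0, _ = ultra.define_regions(g0)
        # same geometry plus a distal (non-proximal) vesicle: band unchanged
        g1 = generate_synapse(p)
        g1.vesicles = [Vesicle(id=0, center=np.array([250., 100., 100.]),
                               equivalent_diameter=48.0,
                               min_az_distance=80.0)]
        az1, _ = ultra.define_regions(g1)
        assert np.array_equal(az0.data, az1.data)

    def test_proximal_vesicle_carves_analytic_cap_volume(self):
        from synaptomo.synth import SynthParams, generate_synapse
        p = SynthParams(contact_radius=80, vesicle_count=0, n_proximal=0,
                        n_az_clusters=1, n_psd_clusters=1, rng_seed=5)
        g0 = generate_synapse(p)
        az0, _ = ultra.define_regions(g0)
        g1 = generate_synapse(p)
        vx = g1.voxel_size
        ext = g1.pre_membrane_mask.physical_extent()
        r = 24.0
        # place a proximal vesicle centred laterally, touching the AZ band
        zlo = np.argwhere(az0.data)[:, 0].min() * vx
        center = np.array([zlo + r - 5.0, ext[1] / 2, ext[2] / 2])
        g1.vesicles = [Vesicle(id=0, center=center, equivalent_diameter=2 * r,
                               min_az_distance=5.0)]
        az1, _ = ultra.define_regions(g1)
        removed = (int(az0.data.sum()) - int(az1.data.sum())) * vx ** 3
        # analytic sphere-slab intersection: cap above the band floor
        h = (center[0] + r) - zlo        # height of sphere above band floor
        h = min(h, 2 * r)
        cap = np.pi * h ** 2 * (r - h / 3.0)
        assert removed == pytest.approx(cap, rel=0.05)


class TestVesicleMetrics:
    def test_voxelized_sphere_diameter(self):
        labels = np.zeros((60, 60, 60), dtype=np.int32)
        c, r = np.array([30., 30., 30.]), 24.0
        g = np.ogrid[:60, :60, :60]
        d2 = sum((gi + 0.5 - ci) ** 2 for gi, ci in zip(g, c))
        labels[d2 <= r * r] = 1
        az = np.zeros_like(labels, dtype=bool)
        az[0] = True
        res = ultra.vesicle_metrics(VoxelVolume(labels, 1.0),
                                    VoxelVolume(az, 1.0))
        assert len(res) == 1
        assert res[0].equivalent_diameter == pytest.approx(48.0, abs=2.0)

    def test_touching_vesicle_is_proximal_with_zero_distance(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[1, 5, 5] = 1
        az = np.zeros_like(labels, dtype=bool)
        az[1, 5, 5] = True
        res = ultra.vesicle_metrics(VoxelVolume(labels, 1.0),
                                    VoxelVolume(az, 1.0))
        assert res[0].min_az_distance == 0.0
        assert res[0].is_proximal

    def test_min_distance_matches_brute_force(self, rng):
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        az = rng.random((12, 12, 12)) < 0.05
        az[0, 0, 0] = True
        for lab in (1, 2, 3):
            k, j, i = rng.integers(0, 12, 3)
            labels[k, j, i] = lab
        res = ultra.vesicle_metrics(VoxelVolume(labels, 1.36),
                                    VoxelVolume(az, 1.36))
        az_pts = np.argwhere(az) * 1.36
        for v in res:
            vox = np.argwhere(labels == v.id + 1) * 1.36
            oracle = min(np.linalg.norm(az_pts - p, axis=1).min() for p in vox)
            assert v.min_az_distance == pytest.approx(oracle, abs=1e-9)

    def test_recovered_diameters_match_generator(self, small_synapse):
        params, geom = small_synapse
        labels = ultra.voxelize_vesicle_labels(geom)
        res = ultra.vesicle_metrics(labels, geom.pre_membrane_mask)
        by_id = {v.id: v for v in res}
        for v in geom.vesicles:
            assert by_id[v.id].equivalent_diameter == pytest.approx(
                v.equivalent_diameter, abs=2 * geom.voxel_size)


class TestProximityHistogram:
    def _vesicles(self, dists):
        return [Vesicle(id=i, center=np.zeros(3), equivalent_diameter=40.0,
                        min_az_distance=d) for i, d in enumerate(dists)]

    def test_counts_and_normalization(self):
        v = self._vesicles([3.0, 7.0, 12.0])
        _, c1 = ultra.proximity_histogram(v, 0.1, bin_width_nm=5.0,
                                          max_dist_nm=50.0)
        assert np.allclose(c1[:4], [1, 1, 1, 0])
        _, c2 = ultra.proximity_histogram(v, 0.05, bin_width_nm=5.0,
                                          max_dist_nm=50.0)
        assert np.allclose(c2[:4], [2, 2, 2, 0])

    def test_conservation(self, rng):
        dists = rng.uniform(0, 480, size=37)
        v = self._vesicles(dists)
        area = 0.231
        _, counts = ultra.proximity_histogram(v, area)
        assert counts.sum() * (area / 0.1) == pytest.approx(37.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ultra.proximity_histogram([], 0.0)


def test_full_report(small_synapse):
    params, geom = small_synapse
    report = ultra.compute_report(geom)
    assert report.cleft_width_mean == pytest.approx(24.4, abs=1.4)
    assert report.az_area > 0
    assert report.vesicle_count == params.vesicle_count
    assert report.mean_vesicle_diameter == pytest.approx(
        params.vesicle_diameter_mean, abs=params.vesicle_diameter_sd)
    d = report.to_dict()
    assert d["vesicle_count"] == params.vesicle_count
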