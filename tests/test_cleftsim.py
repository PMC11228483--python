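import math

import numpy as np
import pytest
from scipy import stats as sstats

from synaptomo import cleftsim as cs
from synaptomo.geometry import Vesicle
from synaptomo.kinetics import KineticScheme, Transition


@pytest.fixture(scope="module")
def scheme():
    return KineticScheme.default()


@pytest.fixture()
def geom():
    return cs.CleftGeometry(cleft_width=24.4, radius=178.4,
                            patches=np.array([[0.0, 0.0, 30.0],
                                              [80.0, 80.0, 30.0],
                                              [-90.0, 40.0, 30.0]]))


class TestConfigAndHelpers:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            cs.SimConfig(dt_us=0)
        with pytest.raises(ValueError):
            cs.SimConfig(clustered_fraction=1.5)
        with pytest.raises(ValueError):
            cs.SimConfig(d_glu=-1)

    def test_default_step_count(self):
        assert cs.SimConfig().n_steps == 10_000

    def test_vesicular_concentration_is_about_100_mM(self):
        assert cs.vesicular_concentration_mM(3500, 48.0) == pytest.approx(
            100.0, rel=0.05)

    def test_smoluchowski_radius_far_below_cleft(self, scheme):
        b = cs.smoluchowski_radius_nm(scheme.binding_rate_of(0), 300.0)
        assert b < 0.01   # reaction-limited regime

    def test_capture_radius_exceeding_half_cleft_is_config_error(self, geom,
                                                                 scheme):
        cfg = cs.SimConfig(capture_radius_nm=20.0, n_seeds=1, t_total_ms=0.1)
        with pytest.raises(ValueError):
            cs.run_single(geom, np.zeros(2), scheme, cfg, "random",
                          np.random.default_rng(0))


class TestSeedReceptors:
    def test_density_times_area_count(self, geom):
        cfg = cs.SimConfig()
        pos, _ = cs.seed_receptors(geom, cfg, "random",
                                   np.random.default_rng(0))
        assert len(pos) == round(1500.0 * geom.psd_area_um2)
        assert len(pos) == 150

    def test_clustered_split_round_half_even(self, geom):
        cfg = cs.SimConfig()
        pos, flags = cs.seed_receptors(geom, cfg, "clustered",
                                       np.random.default_rng(0))
        assert flags.sum() == 112 and (~flags).sum() == 38  # 0.75*150 = 112.5
        assert geom.in_patch(pos[flags]).all()
        assert not geom.in_patch(pos[~flags]).any()

    def test_random_mode_patch_occupancy_matches_area_fraction(self, geom):
        cfg = cs.SimConfig()
        patch_area = np.pi * (geom.patches[:, 2] ** 2).sum()
        frac = patch_area / (np.pi * geom.radius ** 2)
        pvals = []
        for seed in range(100):
            pos, _ = cs.seed_receptors(geom, cfg, "random",
                                       np.random.default_rng(seed))
            n_in = int(cs.CleftGeometry.in_patch(geom, pos).sum())
            pvals.append(sstats.binomtest(n_in, len(pos), frac).pvalue)
        assert np.mean(np.array(pvals) < 0.01) <= 0.05

    def test_clustered_mode_requires_patches(self):
        bare = cs.CleftGeometry(cleft_width=24.0, radius=100.0)
        with pytest.raises(ValueError):
            cs.seed_receptors(bare, cs.SimConfig(), "clustered",
                              np.random.default_rng(0))


class TestReleaseGlutamate:
    def test_point_source_count_and_location(self, geom):
        ves = Vesicle(id=0, center=np.array([200.0, 40.0, 10.0]),
                      equivalent_diameter=48.0, min_az_distance=3.0)
        pos = cs.release_glutamate(ves, geom, 3500)
        assert pos.shape == (3500, 3)
        assert np.allclose(pos[:, 1:], [40.0, 10.0])
        assert np.all(pos[:, 0] <= geom.cleft_width)

    def test_non_proximal_vesicle_rejected(self, geom):
        ves = Vesicle(id=1, center=np.zeros(3), equivalent_diameter=48.0,
                      min_az_distance=50.0)
        with pytest.raises(ValueError):
            cs.release_glutamate(ves, geom)

    def test_out_of_cleft_release_rejected(self, geom):
        with pytest.raises(ValueError):
            cs.release_glutamate(np.array([geom.radius + 100.0, 0.0]), geom)


class TestDiffusion:
    def test_free_msd_matches_einstein_relation(self):
        rng = np.random.default_rng(1)
        pos = np.zeros((10_000, 3))
        D, t = 300.0, 40.0
        for _ in range(40):
            pos = cs.brownian_step(pos, D, 1.0, rng)
        msd = float(np.mean(np.sum(pos ** 2, axis=1)))
        assert msd == pytest.approx(6 * D * t, rel=0.03)

    def test_fold_slab_bounds_and_symmetry(self, rng):
        z = rng.normal(0, 50, 10_000)
        f = cs._fold_slab(z, 24.0)
        assert np.all((f >= 0) & (f <= 24.0))
        # folding is an involution-compatible reflection: already-inside
        # coordinates are untouched
        inside = rng.uniform(0, 24.0, 100)
        assert np.allclose(cs._fold_slab(inside, 24.0), inside)

    def test_reflective_slab_equilibrium_uniform(self):
        """Particle z-distribution in the cleft is uniform at steady state."""
        rng = np.random.default_rng(3)
        z = np.full(4000, 12.0)
        for _ in range(200):
            z = cs._fold_slab(z + rng.normal(0, 2.0, z.shape), 24.0)
        ks = sstats.kstest(z / 24.0, "uniform")
        assert ks.pvalue > 0.01

    def test_disk_reflection_keeps_points_inside(self, rng):
        pts = rng.normal(0, 120, size=(2000, 2))
        ref = cs._reflect_disk(pts, 100.0, np.zeros(2))
        assert np.all(np.hypot(ref[:, 0], ref[:, 1]) <= 100.0 + 1e-9)


class TestReact:
    def test_all_rates_zero_no_state_changes(self, rng):
        s = KineticScheme(["C0", "C1", "C2", "O", "D1", "D2"],
                          [Transition("C0", "C1", 0.0, "glutamate-binding"),
                           Transition("C2", "O", 0.0, "unimolecular")])
        states = np.zeros(50, dtype=np.int64)
        pos3 = np.column_stack([np.zeros(50), rng.uniform(0, 50, (50, 2))])
        glu = rng.uniform(0, 50, size=(200, 3))
        new, consumed = cs.react(states, pos3, glu, s, 1.0, rng, 5.0)
        assert np.array_equal(new, states) and len(consumed) == 0

    def test_zero_glutamate_keeps_resting_state(self, scheme, rng):
        states = np.zeros(100, dtype=np.int64)
        pos3 = np.zeros((100, 3))
        for _ in range(200):
            states, _ = cs.react(states, pos3, np.empty((0, 3)), scheme,
                                 1.0, rng, 5.0)
        assert np.all(states == scheme.resting_index)

    def test_unimolecular_dwell_times_exponential(self, rng):
        """O -> C2 dwell time has mean 1/rate within 5%."""
        rate = 900.0
        s = KineticScheme(["C0", "C1", "C2", "O", "D1", "D2"],
                          [Transition("O", "C2", rate, "unimolecular")])
        n = 20_000
        states = np.full(n, s.index["O"], dtype=np.int64)
        dt = 10.0   # us
        remaining = np.full(n, -1.0)
        t = 0.0
        for step in range(1, 4000):
            states = cs.unimolecular_step(states, s, dt, rng)
            left = (states == s.index["C2"]) & (remaining < 0)
            remaining[left] = step * dt
            if (remaining > 0).all():
                break
        mean_dwell_s = remaining.mean() * 1e-6
        assert mean_dwell_s == pytest.approx(1.0 / rate, rel=0.05)

    def test_binding_consumes_molecule(self, scheme, rng):
        states = np.zeros(30, dtype=np.int64)
        pos3 = np.column_stack([np.zeros(30),
                                rng.uniform(-20, 20, size=(30, 2))])
        glu = np.column_stack([rng.uniform(0, 4, 400),
                               rng.uniform(-20, 20, size=(400, 2))])
        total_bound = 0
        for _ in range(50):
            states, consumed = cs.binding_step(states, pos3, glu, scheme,
                                               1.0, rng, 5.0)
            if len(consumed):
                keep = np.ones(len(glu), bool)
                keep[consumed] = False
                glu = glu[keep]
                total_bound += len(consumed)
        n_transitions = int(np.sum(states != 0) + np.sum(states >= 2))
        assert total_bound >= 1
        assert len(glu) == 400 - total_bound


class TestRunVesicle:
    def test_trace_length_and_conservation(self, geom, scheme):
        cfg = cs.SimConfig(n_seeds=2, t_total_ms=10.0, rng_seed=3)
        tc = cs.run_vesicle(geom, np.zeros(2), scheme, cfg, "random",
                            keep_seeds=True)
        assert len(tc.times_ms) == 10_001
        assert tc.per_seed.shape == (2, 10_001)
        assert tc.peak >= 0
        assert tc.n_receptors == 150

    def test_zero_glutamate_flat_zero_trace(self, geom, scheme):
        cfg = cs.SimConfig(n_seeds=1, t_total_ms=1.0, n_glutamate=0)
        tc = cs.run_vesicle(geom, np.zeros(2), scheme, cfg, "random")
        assert np.all(tc.open_count == 0)

    def test_same_seed_reproducible(self, geom, scheme):
        cfg = cs.SimConfig(n_seeds=2, t_total_ms=1.0, rng_seed=11)
        a = cs.run_vesicle(geom, np.zeros(2), scheme, cfg, "random")
        b = cs.run_vesicle(geom, np.zeros(2), scheme, cfg, "random")
        assert np.array_equal(a.open_count, b.open_count)

    def test_vesicle_over_patch_clustered_beats_random(self, geom, scheme):
        cfg = cs.SimConfig(n_seeds=6, t_total_ms=3.0, rng_seed=5)
        over_patch = np.zeros(2)    # directly above the patch at the origin
        r = cs.run_vesicle(geom, over_patch, scheme, cfg, "random")
        c = cs.run_vesicle(geom, over_patch, scheme, cfg, "clustered")
        assert c.peak > r.peak

    def test_peak_decreases_with_vesicle_patch_offset(self, scheme):
        """Peak response is monotone (in the mean) in the lateral offset
        between release site and the single receptor patch."""
        geom1 = cs.CleftGeometry(cleft_width=24.4, radius=178.4,
                                 patches=np.array([[0.0, 0.0, 40.0]]))
        cfg = cs.SimConfig(n_seeds=10, t_total_ms=3.0, rng_seed=9)
        peaks = []
        for offset in (0.0, 40.0, 80.0, 120.0, 160.0):
            tc = cs.run_vesicle(geom1, np.array([0.0, offset]), scheme, cfg,
                                "clustered")
            peaks.append(tc.peak)
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))
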