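import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rpk.constants import rt
from rpk.io_formats import UmbrellaMetadata, ValidationError
from rpk.synthetic_data import (
    STATE_ASSIST,
    STATE_NONPROD,
    STATE_SINGLE,
    ActiveSiteFixtureSpec,
    ChargeFixtureSpec,
    ConstructionError,
    DoubleWell1D,
    GaussianSum2D,
    MembraneFixtureSpec,
    default_2d_surface,
    eval_surface,
    gen_active_site_trajectory,
    gen_charge_states,
    gen_membrane_trajectory,
    sample_biased_windows,
)


class FlatSurface:
    ndim = 1

    def energy(self, x):
        return 0.0 * np.asarray(x, dtype=float) if np.ndim(x) else 0.0

    def energy_scalar(self, x):
        return 0.0

    def gradient(self, x):
        return 0.0 * np.asarray(x, dtype=float) if np.ndim(x) else 0.0


class TestMembraneGenerator:
    def test_zero_noise_limit_plants_exact_geometry(self):
        spec = MembraneFixtureSpec(n_frames=3, n_lipids_per_leaflet=10,
                                   plane_z=20.0, plane_sigma=0.0,
                                   residue_depths={1: (2.0, 0.0)}, seed=0)
        traj = gen_membrane_trajectory(spec)
        upper = traj.selection("upper_leaflet_P")
        assert np.allclose(traj.coords[:, upper, 2], 20.0)
        marker = traj.selection("residue_cog_markers")
        assert np.allclose(traj.coords[:, marker, 2], 18.0)

    def test_same_seed_bit_identical(self):
        spec = MembraneFixtureSpec(n_frames=5, seed=123,
                                   residue_depths={1: (2.0, 0.3)})
        a = gen_membrane_trajectory(spec)
        b = gen_membrane_trajectory(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_plane_spread_recovered_at_large_n(self):
        spec = MembraneFixtureSpec(n_frames=2000, n_lipids_per_leaflet=40,
                                   plane_sigma=1.0, seed=5)
        traj = gen_membrane_trajectory(spec)
        z = traj.coords[:, traj.selection("upper_leaflet_P"), 2]
        assert z.std() == pytest.approx(1.0, abs=0.05)


class TestActiveSiteGenerator:
    def test_degenerate_mixture_classifies_single_water(self):
        distances = {
            s: {k: (m, 0.0) for k, (m, _) in d.items()}
            for s, d in ActiveSiteFixtureSpec().state_distances.items()}
        spec = ActiveSiteFixtureSpec(n_frames=50,
                                     state_probabilities=(1.0, 0.0, 0.0),
                                     state_distances=distances, seed=1)
        ens = gen_active_site_trajectory(spec)
        from rpk.conformations import catalytic_distances, classify

        recs, summary = classify(catalytic_distances(ens.trajectory,
                                                     ens.atom_map))
        assert summary.loc[STATE_SINGLE, "fraction"] == 1.0

    def test_same_seed_bit_identical(self):
        spec = ActiveSiteFixtureSpec(n_frames=20, seed=9)
        a = gen_active_site_trajectory(spec)
        b = gen_active_site_trajectory(spec)
        assert np.array_equal(a.trajectory.coords, b.trajectory.coords)
        assert np.array_equal(a.labels, b.labels)

    def test_mixture_fractions_converge(self, active_site_5000):
        labels = active_site_5000.labels
        assert np.mean(labels == STATE_SINGLE) == pytest.approx(0.75, abs=0.02)
        assert np.mean(labels == STATE_ASSIST) == pytest.approx(0.04, abs=0.02)
        assert np.mean(labels == STATE_NONPROD) == pytest.approx(0.21, abs=0.02)

    def test_contradictory_distances_raise_construction_error(self):
        distances = {
            s: {k: (m, 0.0) for k, (m, _) in d.items()}
            for s, d in ActiveSiteFixtureSpec().state_distances.items()}
        distances[STATE_SINGLE]["nd_h"] = (1.0, 0.0)
        distances[STATE_SINGLE]["o_h"] = (10.0, 0.0)
        spec = ActiveSiteFixtureSpec(n_frames=5,
                                     state_probabilities=(1.0, 0.0, 0.0),
                                     state_distances=distances, seed=0)
        with pytest.raises(ConstructionError, match="triple"):
            gen_active_site_trajectory(spec)

    def test_bulk_waters_respect_exclusion_zone(self):
        ens = gen_active_site_trajectory(ActiveSiteFixtureSpec(n_frames=10,
                                                               seed=2))
        traj = ens.trajectory
        bulk_o = ens.atom_map["water_o"][2:]
        nd = traj.coords[:, 0, :]
        c = traj.coords[:, 1, :]
        d_nd = np.linalg.norm(traj.coords[:, bulk_o, :] - nd[:, None], axis=2)
        d_c = np.linalg.norm(traj.coords[:, bulk_o, :] - c[:, None], axis=2)
        assert d_nd.min() >= 6.0 and d_c.min() >= 6.0

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            ActiveSiteFixtureSpec(state_probabilities=(0.5, 0.2, 0.2))


class TestBiasedSampler:
    def test_flat_surface_harmonic_stationary_law(self):
        # stationary distribution under bias alone: N(center, RT/k)
        meta = UmbrellaMetadata([("w", 1.5, 100.0)])
        (ts,) = sample_biased_windows(FlatSurface(), meta, n_steps=10_000,
                                      seed=3)
        expected_var = rt(310.15) / 100.0
        assert ts.values.mean() == pytest.approx(1.5, abs=0.01)
        assert ts.values.var() == pytest.approx(expected_var, rel=0.1)

    def test_flat_surface_passes_ks_against_analytic_gaussian(self):
        meta = UmbrellaMetadata([("w", 0.0, 100.0)])
        (ts,) = sample_biased_windows(FlatSurface(), meta, n_steps=10_000,
                                      seed=4)
        sigma = np.sqrt(rt(310.15) / 100.0)
        stat, p = stats.kstest(ts.values, "norm", args=(0.0, sigma))
        assert p > 0.01

    def test_double_well_window_chain_overlaps(self):
        surf = DoubleWell1D(barrier=8.0, well_separation=3.0)
        centers = np.linspace(-1.8, 1.8, 12)
        meta = UmbrellaMetadata([(f"w{i}", float(c), 100.0)
                                 for i, c in enumerate(centers)])
        series = sample_biased_windows(surf, meta, n_steps=2000, seed=5)
        for a, b in zip(series[:-1], series[1:]):
            lo = max(a.values.min(), b.values.min())
            hi = min(a.values.max(), b.values.max())
            assert hi > lo  # every window shares support with a neighbour

    def test_seeded_repeatability(self):
        meta = UmbrellaMetadata([("w", 0.5, 50.0)])
        a = sample_biased_windows(FlatSurface(), meta, n_steps=500, seed=6)
        b = sample_biased_windows(FlatSurface(), meta, n_steps=500, seed=6)
        assert np.array_equal(a[0].values, b[0].values)

    def test_invalid_step_size_rejected(self):
        meta = UmbrellaMetadata([("w", 0.0, 50.0)])
        with pytest.raises(ValidationError):
            sample_biased_windows(FlatSurface(), meta, n_steps=10,
                                  step_size=0.0)


class TestSurfaces:
    def test_double_well_symmetry_point(self):
        s = DoubleWell1D(barrier=12.0, well_separation=4.0)
        e, g = eval_surface(s, 0.0)
        assert e == pytest.approx(12.0)
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_double_well_plants_features_exactly(self):
        s = DoubleWell1D(barrier=17.0, well_separation=3.0, delta_g=-7.9)
        assert s.energy(s.x_reactant) == pytest.approx(0.0)
        assert s.energy(s.x_product) == pytest.approx(-7.9)
        assert s.energy(s.x_ts) == pytest.approx(17.0)

    def test_gaussian_amplitude_at_center(self):
        s = GaussianSum2D([3.5], [[1.0, -2.0]], [0.7])
        assert s.energy(np.array([1.0, -2.0])) == pytest.approx(3.5)

    @given(st.floats(-2.4, 2.4).filter(
        lambda x: min(abs(x - 1.5), abs(x + 1.5)) > 1e-3))
    def test_double_well_gradient_matches_finite_differences(self, x):
        # wall junctions at ±1.5 are C¹ only, so FD windows avoid them
        s = DoubleWell1D(barrier=17.0, well_separation=3.0, delta_g=-7.9)
        h = 1e-6
        fd = (s.energy(x + h) - s.energy(x - h)) / (2 * h)
        scale = max(1.0, abs(fd))
        assert abs(s.gradient(x) - fd) / scale < 1e-6

    @given(st.floats(-2.4, 2.4), st.floats(-2.4, 2.4))
    def test_gaussian_sum_gradient_matches_finite_differences(self, x, y):
        s = default_2d_surface()
        p = np.array([x, y])
        h = 1e-6
        g = s.gradient(p)
        for dim in range(2):
            dp = np.zeros(2)
            dp[dim] = h
            fd = (s.energy(p + dp) - s.energy(p - dp)) / (2 * h)
            assert abs(g[dim] - fd) / max(1.0, abs(fd)) < 1e-6

    def test_scalar_fast_path_agrees_with_array_path(self):
        s = DoubleWell1D(barrier=17.0, well_separation=3.0, delta_g=-7.9)
        xs = np.linspace(-2.5, 2.5, 101)
        fast = np.array([s.energy_scalar(float(x)) for x in xs])
        np.testing.assert_allclose(fast, s.energy(xs), atol=1e-12)


class TestChargeFixture:
    def test_reproducible_and_disjoint(self):
        a = gen_charge_states(ChargeFixtureSpec(seed=8))
        b = gen_charge_states(ChargeFixtureSpec(seed=8))
        np.testing.assert_array_equal(a[0][1], b[0][1])
        assert [g.label for g in a[2]] == [g.label for g in b[2]]

    def test_qm_region_is_neutral(self):
        (q, _), _, _ = gen_charge_states(ChargeFixtureSpec(seed=1))
        assert q.sum() == pytest.approx(0.0, abs=1e-12)
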