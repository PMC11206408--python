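import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def active_site_5000():
    """Seeded catalytic-microstate ensemble at the planted study conditions:
    state probabilities (0.75, 0.04, 0.21) and water–Ca²⁺ distance laws
    N(3.6, 1.5) / N(4.8, 0.2) Å, 5000 frames."""
    from rpk.synthetic_data import ActiveSiteFixtureSpec, gen_active_site_trajectory

    return gen_active_site_trajectory(
        ActiveSiteFixtureSpec(n_frames=5000, seed=42))


@pytest.fixture(scope="session")
def classified_5000(active_site_5000):
    from rpk.conformations import catalytic_distances, classify

    recs = catalytic_distances(active_site_5000.trajectory,
                               active_site_5000.atom_map)
    recs, summary = classify(recs)
    return recs, summary


@pytest.fixture(scope="session")
def planted_double_well_profile():
    """WHAM reconstruction of a planted 17.0 / −7.9 kcal mol⁻¹ double well
    from 24 umbrella windows (k = 100 kcal mol⁻¹ Å⁻², 10⁴ retained samples
    per window)."""
    from rpk.free_energy import UmbrellaWindow, wham_solve
    from rpk.io_formats import UmbrellaMetadata
    from rpk.synthetic_data import DoubleWell1D, sample_biased_windows

    surface = DoubleWell1D(barrier=17.0, well_separation=3.0, delta_g=-7.9)
    centers = np.linspace(-1.9, 1.9, 24)
    meta = UmbrellaMetadata([(f"window_{i}", float(c), 100.0)
                             for i, c in enumerate(centers)])
    series = sample_biased_windows(surface, meta, n_steps=12500, seed=7)
    windows = [UmbrellaWindow(s, e[1], e[2], discard_fraction=0.0)
               for s, e in zip(series, meta.entries)]
    return surface, wham_solve(windows, bin_width=0.05)


@pytest.fixture(scope="session")
def surface_2d_oracle():
    """Dense-grid stationary points of the default 2-D test surface
    (independent of the NEB implementation)."""
    from rpk.pathfinding import grid_stationary_points
    from rpk.synthetic_data import default_2d_surface

    surface = default_2d_surface()
    minima, saddles = grid_stationary_points(
        surface, ((-2.5, 2.5), (-2.5, 2.5)), n_grid=201)
    return surface, minima, saddles


@pytest.fixture(scope="session")
def membrane_hotspot_fixture():
    """Membrane trajectory with five planted contiguous buried runs."""
    from rpk.synthetic_data import MembraneFixtureSpec, gen_membrane_trajectory

    runs = [(1, 2, 3), (16, 17, 18, 19), (30,), (62, 63, 64),
            (111, 112, 113, 114)]
    depths = {rid: (-2.0, 0.5) for rid in range(1, 125)}
    for run in runs:
        for rid in run:
            depths[rid] = (4.0, 0.5)
    spec = MembraneFixtureSpec(n_frames=200, n_lipids_per_leaflet=60,
                               plane_z=20.0, plane_sigma=1.5,
                               residue_depths=depths, seed=11)
    return gen_membrane_trajectory(spec), runs
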