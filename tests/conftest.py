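import numpy as np
import pytest

import phenoprofiles as pp
from phenoprofiles.growth import GrowthModel
from phenoprofiles.scene import render_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """24-plot noiseless scene with known truth, shared across tests."""
    design = pp.make_field_design(24, seed=0)
    model = GrowthModel(height_noise_sd=0.0, lodging_fraction=0.0)
    heights, _ = pp.simulate_growth_profiles(design, model, seed=1)
    scene = render_scene(design, heights, cell_size_m=0.025, seed=2)
    return scene


@pytest.fixture()
def flat_plane_cloud():
    """10k points on the exact plane z = 5 over a 10 m x 10 m square."""
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 10, size=(10_000, 2))
    xyz = np.column_stack([xy, np.full(len(xy), 5.0)])
    return pp.PointCloud(xyz)


def make_ph_profiles(n, seed=0, days=(24, 45, 57, 74, 81)):
    """Random monotone PH profiles for property tests."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        final = rng.uniform(150, 300)
        increments = rng.dirichlet(np.ones(len(days))) * final
        values = np.cumsum(increments)
        profiles.append(pp.TemporalProfile(
            plot_id=f"P{i:04d}", background="mixed", days=days,
            values=values, trait_name="PH"))
    return profiles
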