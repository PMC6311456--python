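import pytest

from fibermix import neural as nr
from fibermix import optics as opt
from fibermix import pipeline as pl


@pytest.fixture(scope="session")
def kernel():
    return nr.gcamp_kernel()


@pytest.fixture(scope="session")
def small_grid():
    """0.5-mm cube of 5-um voxels: cheap but fine-grained enough for MC tests."""
    return opt.VoxelGrid(voxel_size=0.005, dims=(100, 100, 100))


@pytest.fixture(scope="session")
def launch():
    return opt.LaunchSpec()


@pytest.fixture(scope="session")
def water_profile(launch, small_grid):
    return opt.simulate_fluence(200_000, launch, opt.WATER, small_grid,
                                seed=11, wavelength="water")


@pytest.fixture(scope="session")
def tissue_profile_small(launch, small_grid):
    return opt.simulate_fluence(200_000, launch, opt.TISSUE_490, small_grid,
                                seed=12, wavelength="490nm")


@pytest.fixture(scope="session")
def scenario_profiles():
    """Full-scale (1e6 packet, 1-mm grid) excitation/collection profiles.

    Session-scoped: built once and shared by every interface-statistics and
    end-to-end test.
    """
    return pl.compute_profiles(pl.ScenarioConfig())


@pytest.fixture(scope="session")
def toy_mix():
    return pl.make_toy_fixture().mixing
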