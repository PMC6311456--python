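"""Bundle geometry, mixing matrix, and interface-statistics tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibermix import bundle as bnd
from fibermix import optics as opt


def _uniform_profile(value=2.0, dims=(10, 10, 10), voxel=0.01):
    """Constant-valued profile: interpolation inside the grid is exact."""
    grid = opt.VoxelGrid(voxel_size=voxel, dims=dims)
    return opt.FluenceProfile(grid=grid, values=np.full(dims, value),
                              wavelength="test", n_packets=1, seed=0)


def _point_profile(dims=(11, 11, 11), voxel=0.01):
    grid = opt.VoxelGrid(voxel_size=voxel, dims=dims)
    vals = np.zeros(dims)
    vals[5, 5, 5] = 1.0
    return opt.FluenceProfile(grid=grid, values=vals, wavelength="test",
                              n_packets=1, seed=0)


class TestFiberSampling:
    def test_zero_spread_gives_coincident_tips(self):
        layout = bnd.sample_fiber_positions(8, sigma_xy=0.0, sigma_z=0.0, seed=1)
        assert np.allclose(layout.positions, 0.0)

    def test_empirical_spread_matches_sigma(self):
        n = 10_000
        layout = bnd.sample_fiber_positions(n, sigma_xy=0.150, sigma_z=0.015,
                                            seed=2)
        sd_x = layout.positions[:, 0].std()
        sd_z = layout.positions[:, 2].std()
        se = 0.150 / np.sqrt(2 * n)
        assert abs(sd_x - 0.150) < 3 * se
        assert abs(sd_z - 0.015) < 3 * 0.015 / np.sqrt(2 * n)

    def test_reproducible_and_seed_sensitive(self):
        a = bnd.sample_fiber_positions(100, seed=3).positions
        b = bnd.sample_fiber_positions(100, seed=3).positions
        c = bnd.sample_fiber_positions(100, seed=4).positions
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            bnd.sample_fiber_positions(0)
        with pytest.raises(ValueError):
            bnd.sample_fiber_positions(10, sigma_xy=-1.0)


class TestNeuronSampling:
    def test_count_is_density_times_volume(self):
        box = ((-0.5, 0.5),) * 3  # 1 mm^3
        pop = bnd.sample_neuron_positions(250_000.0, box, seed=1)
        assert pop.n_neurons == 250_000
        # default ~1.2 mm^3 box gives the 300k population
        pop = bnd.sample_neuron_positions(seed=1)
        assert pop.n_neurons == pytest.approx(300_000, abs=1500)

    def test_positions_inside_box(self):
        box = ((0.0, 0.1), (-0.2, 0.0), (1.0, 1.5))
        pop = bnd.sample_neuron_positions(5e4, box, seed=2)
        lo = pop.positions.min(axis=0)
        hi = pop.positions.max(axis=0)
        assert (lo >= [0.0, -0.2, 1.0]).all() and (hi <= [0.1, 0.0, 1.5]).all()

    def test_zero_density_gives_empty_population(self):
        pop = bnd.sample_neuron_positions(0.0, ((-1, 1),) * 3, seed=3)
        assert pop.n_neurons == 0

    def test_two_seeds_same_count_different_positions(self):
        p1 = bnd.sample_neuron_positions(1e4, seed=1)
        p2 = bnd.sample_neuron_positions(1e4, seed=2)
        assert p1.n_neurons == p2.n_neurons
        assert not np.array_equal(p1.positions, p2.positions)


class TestProfileLookup:
    def test_voxel_center_returns_stored_value(self):
        # center voxel of the 11^3 grid sits exactly at the tip
        prof = _point_profile()
        val = bnd.profile_lookup(prof, (0, 0, 0), (0.0, 0.0, 0.0))
        assert val[0] == pytest.approx(1.0)

    def test_outside_grid_returns_zero(self):
        prof = _point_profile()
        assert bnd.profile_lookup(prof, (0, 0, 0), (1.0, 1.0, 1.0))[0] == 0.0

    def test_midpoint_averages_neighbors(self):
        prof = _point_profile()
        mid = bnd.profile_lookup(prof, (0, 0, 0), (0.0, 0.0, 0.005))
        assert mid[0] == pytest.approx(0.5)

    def test_fiber_tip_offset_shifts_frame(self):
        prof = _point_profile()
        val = bnd.profile_lookup(prof, (0.1, 0.0, 0.0), (0.1, 0.0, 0.0))
        assert val[0] == pytest.approx(1.0)


class TestMixingMatrix:
    def test_single_neuron_under_single_fiber_normalizes_to_one(self):
        prof = _uniform_profile(3.0)
        layout = bnd.sample_fiber_positions(1, 0.0, 0.0, seed=0)
        pop = bnd.NeuronPopulation(positions=np.array([[0.0, 0.0, 0.005]]),
                                   density=1.0, box=((-1, 1),) * 3, seed=0)
        mix = bnd.build_mixing_matrix(layout, pop, prof, prof)
        assert mix.normalized[0, 0] == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # uniform profiles make g and h constant inside the grid; Eq. M = h*sum(g)
        exc = _uniform_profile(2.0)
        col = _uniform_profile(5.0)
        layout = bnd.sample_fiber_positions(2, 0.0, 0.0, seed=0)
        pop = bnd.NeuronPopulation(
            positions=np.array([[0.0, 0.0, 0.02], [0.0, 0.0, -0.02]]),
            density=1.0, box=((-1, 1),) * 3, seed=0)
        mix = bnd.build_mixing_matrix(layout, pop, exc, col)
        # each neuron sees g=2 from each of 2 fibers -> sum 4; h=5
        assert np.allclose(mix.M, 20.0)
        assert np.allclose(mix.excitation_sums, 4.0)
        assert np.allclose(mix.g, 2.0) and np.allclose(mix.h, 5.0)

    def test_empty_population_degenerates_cleanly(self):
        prof = _uniform_profile()
        layout = bnd.sample_fiber_positions(3, seed=0)
        pop = bnd.sample_neuron_positions(0.0, ((-1, 1),) * 3, seed=0)
        mix = bnd.build_mixing_matrix(layout, pop, prof, prof)
        assert mix.M.shape == (3, 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 5), st.integers(2, 6), st.integers(0, 1000))
    def test_factorization_identity_vs_bruteforce(self, n_fib, n_neu, seed):
        # M[i,j] == h[i,j] * sum_k g[j,k] element by element
        rng = np.random.default_rng(seed)
        g = rng.random((n_neu, n_fib))
        h = rng.random((n_fib, n_neu))
        M = np.empty((n_fib, n_neu))
        for i in range(n_fib):
            for j in range(n_neu):
                M[i, j] = h[i, j] * sum(g[j, k] for k in range(n_fib))
        mix = bnd.MixingMatrix(M=h * g.sum(axis=1)[None, :], h=h, g=g,
                               excitation_sums=g.sum(axis=1), normalization=1.0)
        assert np.allclose(mix.M, M)
        assert (mix.M >= 0).all()

    def test_real_profile_mixing_nonnegative(self, tissue_profile_small):
        layout = bnd.sample_fiber_positions(5, seed=1)
        pop = bnd.sample_neuron_positions(2e4, ((-0.2, 0.2),) * 3, seed=1)
        mix = bnd.build_mixing_matrix(layout, pop, tissue_profile_small,
                                      tissue_profile_small)
        assert (mix.M >= 0).all()
        assert np.allclose(mix.M, mix.h * mix.excitation_sums[None, :])


class TestVisibilityStats:
    def _mix(self, M):
        M = np.asarray(M, dtype=float)
        return bnd.MixingMatrix(M=M, h=None, g=None,
                                excitation_sums=np.ones(M.shape[1]),
                                normalization=1.0)

    def test_threshold_zero_counts_every_nonzero_neuron(self):
        mix = self._mix([[0.5, 0.0, 0.2], [0.0, 0.0, 0.3]])
        stats = bnd.visibility_stats(mix, thresholds=(1e-12,))
        assert stats[0]["n_ge1"] == 2

    def test_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        mix = self._mix(rng.random((10, 200)))
        stats = bnd.visibility_stats(mix, thresholds=(0.005, 0.01, 0.02, 0.05))
        ge1 = [s["n_ge1"] for s in stats]
        ge2 = [s["n_ge2"] for s in stats]
        assert ge1 == sorted(ge1, reverse=True)
        assert ge2 == sorted(ge2, reverse=True)
        assert all(b <= a for a, b in zip(ge1, ge2))

    def test_single_fiber_has_no_multifiber_neurons(self):
        mix = self._mix([[1.0, 0.5, 0.0]])
        stats = bnd.visibility_stats(mix, thresholds=(0.01,))
        assert stats[0]["n_ge2"] == 0 and stats[0]["n_ge1"] == 2


class TestContributionCurves:
    def _mix(self, M):
        M = np.asarray(M, dtype=float)
        return bnd.MixingMatrix(M=M, h=None, g=None,
                                excitation_sums=np.ones(M.shape[1]),
                                normalization=1.0)

    def test_single_visible_neuron(self):
        curve = bnd.fiber_contribution_curve(self._mix([[3.0, 0.0, 0.0]]), 4)
        assert np.allclose(curve, [1, 0, 0, 0])

    def test_hand_built_ratios(self):
        curve = bnd.fiber_contribution_curve(self._mix([[4.0, 2.0, 1.0]]), 3)
        assert np.allclose(curve, [1.0, 0.5, 0.25])

    def test_curve_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(1)
        curve = bnd.fiber_contribution_curve(self._mix(rng.random((6, 40))), 10)
        assert curve[0] == pytest.approx(1.0)
        assert (np.diff(curve) <= 1e-12).all()

    def test_neuron_collection_hand_built(self):
        mix = self._mix(np.array([[10.0], [5.0]]))
        curve = bnd.neuron_collection_curve(mix, n_neurons=1, n_fibers_shown=2)
        assert np.allclose(curve, [100.0, 50.0])

    def test_neuron_seen_by_one_fiber(self):
        mix = self._mix(np.array([[7.0], [0.0], [0.0]]))
        curve = bnd.neuron_collection_curve(mix, n_neurons=1, n_fibers_shown=3)
        assert np.allclose(curve, [100.0, 0.0, 0.0])

    def test_brightness_dominance_hand_value(self):
        # rows: (4,2) -> 100%; (3,1) -> 200%; mean 150%
        mix = self._mix(np.array([[4.0, 2.0], [1.0, 3.0]]))
        assert bnd.brightness_dominance(mix) == pytest.approx(150.0)


class TestScaleFluence:
    def test_linear_in_power(self, tissue_profile_small):
        one = bnd.scale_fluence(tissue_profile_small, 1.25)
        two = bnd.scale_fluence(tissue_profile_small, 2.5)
        assert np.allclose(two, 2 * one)

    def test_contour_volume_monotone_in_power(self, tissue_profile_small):
        voxel = tissue_profile_small.grid.voxel_size
        vols = [bnd.iso_contour_volume(bnd.scale_fluence(tissue_profile_small, p),
                                       voxel, 2.5) for p in (1.25, 2.5, 5.0)]
        assert vols[0] <= vols[1] <= vols[2]
        assert vols[2] > 0

    def test_nonpositive_power_rejected(self, tissue_profile_small):
        with pytest.raises(ValueError):
            bnd.scale_fluence(tissue_profile_small, 0.0)


class TestSingleFiberReduction:
    def test_one_fiber_collection_curves_are_pure(self, tissue_profile_small):
        # sigma -> 0 with one fiber: classical single-fiber photometry
        layout = bnd.sample_fiber_positions(1, 0.0, 0.0, seed=0)
        pop = bnd.sample_neuron_positions(3e4, ((-0.1, 0.1),) * 3, seed=5)
        mix = bnd.build_mixing_matrix(layout, pop, tissue_profile_small,
                                      tissue_profile_small)
        curve = bnd.neuron_collection_curve(mix, n_neurons=20, n_fibers_shown=3)
        assert np.allclose(curve, [100.0, 0.0, 0.0])
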