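"""Monte Carlo photon-transport unit and property tests."""

import numpy as np
import pytest

from fibermix import optics as opt


RNG = lambda s=0: np.random.default_rng(s)


class TestOpticalProperties:
    def test_presets_match_published_coefficients(self):
        assert opt.TISSUE_490.mu_a == pytest.approx(0.337)
        assert opt.TISSUE_512.mu_a == pytest.approx(0.343)
        assert opt.TISSUE_490.mu_s == 20.0 and opt.TISSUE_490.g == 0.9
        assert opt.WATER.mu_a == 0.0 and opt.WATER.mu_s == 0.0

    @pytest.mark.parametrize("kwargs", [
        {"mu_a": -0.1, "mu_s": 1.0},
        {"mu_a": 0.1, "mu_s": -1.0},
        {"mu_a": 0.1, "mu_s": 1.0, "g": 1.5},
        {"mu_a": 0.1, "mu_s": 1.0, "n_medium": 0.9},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            opt.OpticalProperties(**kwargs)


class TestVoxelGrid:
    def test_extent_is_exactly_dims_times_voxel(self):
        g = opt.VoxelGrid(voxel_size=0.005, dims=(200, 200, 200))
        assert g.extent == (1.0, 1.0, 1.0)
        assert np.allclose(g.origin, [-0.5, -0.5, -0.5])

    def test_axis_coords_centered_on_tip(self):
        g = opt.VoxelGrid(voxel_size=0.01, dims=(4, 4, 4))
        assert np.allclose(g.axis_coords(2), [-0.015, -0.005, 0.005, 0.015])


class TestLaunchDirection:
    def test_zero_na_collapses_to_axis(self):
        launch = opt.LaunchSpec(numerical_aperture=0.0)
        d = opt.sample_launch_direction(launch, opt.TISSUE_490, RNG(), size=100)
        assert np.allclose(d, [0, 0, 1])

    def test_na_exceeding_index_rejected(self):
        launch = opt.LaunchSpec(numerical_aperture=1.5)
        with pytest.raises(ValueError):
            opt.sample_launch_direction(launch, opt.TISSUE_490, RNG())

    def test_angle_statistics_match_direct_sampling_oracle(self):
        # oracle: draw the stated truncated Rayleigh polar angle directly
        launch = opt.LaunchSpec()
        sigma = launch.sigma_theta(opt.TISSUE_490.n_medium)
        n = 100_000
        rng = RNG(7)
        theta_oracle = sigma * np.sqrt(-2 * np.log(rng.random(4 * n)))
        theta_oracle = theta_oracle[theta_oracle < np.pi / 2][:n]
        d = opt.sample_launch_direction(launch, opt.TISSUE_490, RNG(8), size=n)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        theta = np.arccos(np.clip(d[:, 2], -1, 1))
        se = np.hypot(theta.std() / np.sqrt(n), theta_oracle.std() / np.sqrt(n))
        assert abs(theta.mean() - theta_oracle.mean()) < 3 * se
        assert abs(theta.std() - theta_oracle.std()) < 3 * se


class TestStepLength:
    def test_closed_form_single_draw(self):
        # U = e^-1 gives step exactly 1/mu_t
        class FixedRng:
            def random(self, size):
                return np.full(size, 1.0 - np.exp(-1.0))
        assert opt.sample_step_length(1.0, FixedRng())[0] == pytest.approx(1.0)

    def test_mean_free_path(self):
        mu_t = 20.337
        s = opt.sample_step_length(mu_t, RNG(3), size=100_000)
        se = s.std() / np.sqrt(s.size)
        assert abs(s.mean() - 1 / mu_t) < 3 * se

    @pytest.mark.parametrize("mu_t", [0.0, -1.0])
    def test_nonpositive_mu_t_rejected(self, mu_t):
        with pytest.raises(ValueError):
            opt.sample_step_length(mu_t, RNG())


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cosine_equals_anisotropy(self, g):
        inc = np.array([0.0, 0.0, 1.0])
        d = opt.sample_scatter_direction(g, inc, RNG(int(g * 10)), size=100_000)
        cos = d @ inc
        se = cos.std() / np.sqrt(cos.size)
        assert abs(cos.mean() - g) < 3 * se

    def test_forward_limit(self):
        inc = np.array([0.0, 0.0, 1.0])
        d = opt.sample_scatter_direction(1 - 1e-9, inc, RNG(5), size=1000)
        assert (d @ inc > 1 - 1e-6).all()

    def test_tilted_incoming_preserves_unit_norm(self):
        inc = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        d = opt.sample_scatter_direction(0.9, inc, RNG(6), size=5000)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert abs((d @ inc).mean() - 0.9) < 0.01


class TestPacketTransport:
    def test_energy_conservation_per_run(self, launch, small_grid):
        prof = opt.simulate_fluence(20_000, launch, opt.TISSUE_490,
                                    small_grid, seed=42)
        b = prof.bookkeeping
        lhs = b["launched"] + b["roulette_gain"]
        rhs = b["deposited"] + b["escaped"] + b["roulette_killed"]
        assert abs(lhs - rhs) / lhs < 1e-9

    def test_absorption_dominated_limit(self, launch, small_grid):
        # mu_a >> mu_s: essentially all launched weight is absorbed in tissue
        props = opt.OpticalProperties(mu_a=500.0, mu_s=0.5, g=0.9)
        book = opt.propagate_packet(launch, props, small_grid, seed=3)
        assert book["deposited"] > 0.999 * book["launched"]

    def test_single_packet_deterministic(self, launch, small_grid):
        acc1 = np.zeros(small_grid.dims)
        acc2 = np.zeros(small_grid.dims)
        opt.propagate_packet(launch, opt.TISSUE_490, small_grid, seed=9, accumulator=acc1)
        opt.propagate_packet(launch, opt.TISSUE_490, small_grid, seed=9, accumulator=acc2)
        assert np.array_equal(acc1, acc2)
        assert acc1.sum() > 0


def _ballistic_oracle(launch, sigma, z, voxel, n=400_000, seed=123):
    """Direct Monte Carlo of the launch geometry alone (no transport code).

    Tracks where each ballistic ray crosses the plane at depth z and tallies
    path length through the central voxel cross-section, per packet and per
    voxel volume. Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    r = (launch.core_diameter / 2) * np.sqrt(rng.random(n))
    a = 2 * np.pi * rng.random(n)
    theta = sigma * np.sqrt(-2 * np.log(rng.random(n)))
    redraw = theta >= np.pi / 2
    while redraw.any():
        theta[redraw] = sigma * np.sqrt(-2 * np.log(rng.random(int(redraw.sum()))))
        redraw = theta >= np.pi / 2
    phi = 2 * np.pi * rng.random(n)
    x = r * np.cos(a) + z * np.tan(theta) * np.cos(phi)
    y = r * np.sin(a) + z * np.tan(theta) * np.sin(phi)
    half = voxel / 2
    inside = (np.abs(x) < half) & (np.abs(y) < half)
    # track length through the voxel is voxel/cos(theta)
    w = np.where(inside, voxel / np.cos(theta), 0.0) / voxel ** 3
    return w.mean(), w.std() / np.sqrt(n)


class TestFluenceSimulation:
    def test_water_profile_matches_ballistic_closed_form(self, launch,
                                                         water_profile):
        sigma = launch.sigma_theta(opt.WATER.n_medium)
        zc, fz = water_profile.on_axis()
        grid = water_profile.grid
        for z in (0.1025, 0.2025):
            iz = int(np.argmin(np.abs(zc - z)))
            mc = fz[iz]
            oracle, se_o = _ballistic_oracle(launch, sigma, zc[iz],
                                             grid.voxel_size)
            hits = mc * water_profile.n_packets * grid.voxel_size ** 2
            se_mc = mc / np.sqrt(max(hits, 1.0))
            assert abs(mc - oracle) < 3 * (se_mc + se_o), (z, mc, oracle)

    def test_tissue_profile_peaks_at_tip_and_decays(self, tissue_profile_small):
        vals = tissue_profile_small.values
        dims = tissue_profile_small.grid.dims
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        center = (dims[0] // 2, dims[1] // 2, dims[2] // 2)
        assert abs(peak[0] - center[0]) <= 1 and abs(peak[1] - center[1]) <= 1
        assert abs(peak[2] - center[2]) <= 2
        _, fz = tissue_profile_small.on_axis()
        forward = fz[dims[2] // 2:]
        assert forward[0] > forward[20] > forward[45]
        assert (vals >= 0).all()

    def test_profile_reproducible_under_seed(self, launch, small_grid):
        p1 = opt.simulate_fluence(5000, launch, opt.TISSUE_490, small_grid, seed=5)
        p2 = opt.simulate_fluence(5000, launch, opt.TISSUE_490, small_grid, seed=5)
        assert np.array_equal(p1.values, p2.values)

    def test_monte_carlo_convergence(self, launch, small_grid):
        # per-packet-normalized profiles converge ~1/sqrt(N)
        ref = opt.simulate_fluence(160_000, launch, opt.TISSUE_490, small_grid,
                                   seed=21).values
        d = []
        for n, seed in ((10_000, 22), (40_000, 23)):
            p = opt.simulate_fluence(n, launch, opt.TISSUE_490, small_grid,
                                     seed=seed).values
            d.append(np.linalg.norm(p - ref))
        assert d[1] < d[0]

    def test_axial_symmetry(self, tissue_profile_small):
        # x->-x mirror differs only by Monte Carlo noise
        v = tissue_profile_small.values
        sym = np.abs(v - v[::-1, :, :])
        scale = v.max()
        assert np.median(sym[v > 1e-3 * scale] /
                         v[v > 1e-3 * scale]) < 0.5

    def test_tip_outside_grid_rejected(self, small_grid):
        bad = opt.LaunchSpec(tip=(0.0, 0.0, 5.0))
        with pytest.raises(ValueError):
            opt.simulate_fluence(10, bad, opt.TISSUE_490, small_grid, seed=0)

    def test_n_packets_must_be_positive(self, launch, small_grid):
        with pytest.raises(ValueError):
            opt.simulate_fluence(0, launch, opt.TISSUE_490, small_grid, seed=0)


class TestAbsorptionCoefficient:
    def test_zero_blood_volume_gives_zero(self):
        assert opt.compute_absorption_coefficient(0.0, 15.0, 0.7, 490) == 0.0

    def test_full_oxygenation_uses_only_oxyhemoglobin(self):
        full = opt.compute_absorption_coefficient(0.03, 15.0, 1.0, 500)
        half = opt.compute_absorption_coefficient(0.015, 15.0, 1.0, 500)
        assert full == pytest.approx(2 * half)

    def test_physiological_parameters_approximate_preset(self):
        # 3% blood, 15 g/dL, 70% SO2 at 490 nm should land near the preset
        mu_a = opt.compute_absorption_coefficient(0.03, 15.0, 0.7, 490)
        assert mu_a == pytest.approx(0.337, rel=0.20)

    def test_wavelength_outside_table_rejected(self):
        with pytest.raises(ValueError):
            opt.compute_absorption_coefficient(0.03, 15.0, 0.7, 800)
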