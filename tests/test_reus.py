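"""WHAM, window diffusivity, spline fitting and ISDM integration."""

import numpy as np
import pytest
from scipy import integrate

from bmcperm import (DiffusivityProfile, FreeEnergyProfile, PoreSet,
                     UmbrellaWindow, boltzmann_inversion,
                     effective_permeability, fit_profile_spline,
                     isdm_permeability, pmf_2d, wham, window_diffusivity)
from bmcperm.constants import ThermoConstants
from bmcperm.models import UmbrellaPermeability
from bmcperm.reus import diffusivity_profile, read_window_file, write_window_file
from bmcperm.trajectory import ParticleSet, ShellGeometry, Trajectory

from conftest import double_well

KBT = ThermoConstants().kBT
BETA = 1.0 / KBT


def ou_window(tau_ps, var, n, interval_ps, seed, center=0.0, k=5.0):
    """Exact Ornstein-Uhlenbeck discretisation — independent of the BD code."""
    rng = np.random.default_rng(seed)
    a = np.exp(-interval_ps / tau_ps)
    x = np.empty(n)
    x[0] = rng.normal(0, np.sqrt(var))
    noise = rng.standard_normal(n - 1) * np.sqrt(var * (1 - a * a))
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i - 1]
    return UmbrellaWindow(center=center, k=k, samples=center + x,
                          sample_interval=interval_ps)


class TestWham:
    def test_single_unbiased_window_is_boltzmann_inversion(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 1.0, 50_000)
        w = UmbrellaWindow(center=0.0, k=1e-9, samples=samples,
                           sample_interval=1.0)
        prof = wham([w], bin_width=0.25, n_bootstrap=0,
                    trim_to_centers=False)
        counts, edges = np.histogram(samples, bins=np.arange(
            samples.min(), samples.max() + 0.25, 0.25))
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = counts >= max(10, 0.01 * counts.max())
        expected = -KBT * np.log(counts[keep].astype(float))
        expected -= expected.min()
        got = np.interp(mids[keep], prof.grid, prof.G)
        np.testing.assert_allclose(got, expected, atol=0.02)

    def test_flat_profile_reconstructed_flat(self, flat_windows):
        _, wins = flat_windows
        prof = wham(wins, bin_width=0.5, n_bootstrap=0)
        assert np.sqrt(np.mean(prof.G**2)) < 0.1

    def test_double_well_barrier_recovered(self, double_well_windows):
        _, wins = double_well_windows
        prof = wham(wins, bin_width=0.5, n_bootstrap=0)
        truth = double_well(prof.grid)
        truth -= truth.min()
        rms = np.sqrt(np.mean((prof.G - truth) ** 2))
        assert rms < 0.2
        barrier_true = double_well(0.0) - double_well(3.0)
        i0 = np.argmin(np.abs(prof.grid))
        assert prof.G[i0] == pytest.approx(barrier_true, abs=0.2)

    def test_reconstruction_error_shrinks_with_sampling(self,
                                                        double_well_windows):
        from bmcperm import UmbrellaSpec, gen_umbrella_windows
        from conftest import WINDOW_CENTERS, const_D

        spec, wins_big = double_well_windows
        small = UmbrellaSpec(profile_G=double_well, profile_D=const_D(70.0),
                             window_centers=WINDOW_CENTERS, k_bias=5.0,
                             n_samples=1_000, sample_interval=2.0,
                             equil_discard=0.05, seed=5)
        wins_small = gen_umbrella_windows(small)

        def rms(wins):
            prof = wham(wins, bin_width=0.5, n_bootstrap=0)
            truth = double_well(prof.grid)
            truth -= truth.min()
            return np.sqrt(np.mean((prof.G - truth) ** 2))

        assert rms(wins_big) < rms(wins_small)

    def test_disjoint_windows_error_names_gap(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.0, 5.0, rng.normal(0, 0.3, 2000), 1.0)
        w2 = UmbrellaWindow(10.0, 5.0, rng.normal(10, 0.3, 2000), 1.0)
        with pytest.raises(ValueError, match="disjoint.*0.*10"):
            wham([w1, w2], bin_width=0.5, n_bootstrap=0)

    def test_bootstrap_errors_are_positive_and_seeded(self, flat_windows):
        _, wins = flat_windows
        p1 = wham(wins, bin_width=0.5, n_bootstrap=20, seed=3)
        p2 = wham(wins, bin_width=0.5, n_bootstrap=20, seed=3)
        assert np.all(p1.stderr > 0)
        np.testing.assert_array_equal(p1.stderr, p2.stderr)


class TestWindowDiffusivity:
    def test_ou_process_recovery(self):
        """k = 5 kcal/mol/Å², D = 70 Å²/ns → var = k_BT/k, τ = var/D."""
        var = KBT / 5.0                      # ≈ 0.1184 Å²
        d_true = 70.0
        tau_ps = var / d_true * 1e3          # ≈ 1.69 ps
        w = ou_window(tau_ps, var, 200_000, 0.2, seed=4)
        assert np.var(w.samples) == pytest.approx(var, rel=0.05)
        d_est = window_diffusivity(w)
        assert d_est == pytest.approx(d_true, rel=0.15)

    def test_doubling_d_halves_tau(self):
        var = KBT / 5.0
        w_slow = ou_window(var / 70.0 * 1e3, var, 100_000, 0.1, seed=6)
        w_fast = ou_window(var / 140.0 * 1e3, var, 100_000, 0.1, seed=6)
        d_slow = window_diffusivity(w_slow)
        d_fast = window_diffusivity(w_fast)
        assert d_fast / d_slow == pytest.approx(2.0, rel=0.2)

    def test_constant_series_is_an_error(self):
        w = UmbrellaWindow(0.0, 5.0, np.zeros(5000), 0.1)
        with pytest.raises(ValueError, match="variance"):
            window_diffusivity(w)

    def test_too_few_samples_is_an_error(self):
        w = UmbrellaWindow(0.0, 5.0, np.random.default_rng(0).normal(0, 1, 500),
                           0.1)
        with pytest.raises(ValueError, match="1000"):
            window_diffusivity(w)


class TestSplineFit:
    def test_line_is_reproduced(self):
        f = fit_profile_spline([0.0, 1, 2, 3, 4], [1.0, 3, 5, 7, 9])
        x = np.linspace(0, 4, 17)
        np.testing.assert_allclose(f(x), 2 * x + 1, atol=1e-6)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_profile_spline([1.0], [2.0])

    def test_noisy_sine_smoothed_below_noise_level(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 2 * np.pi, 80)
        y = np.sin(x) + rng.normal(0, 0.1, len(x))
        f = fit_profile_spline(x, y)
        assert np.sqrt(np.mean((f(x) - np.sin(x)) ** 2)) < 0.1

    def test_evaluation_clamped_to_data_range(self):
        f = fit_profile_spline([0.0, 1, 2, 3], [0.0, 1, 2, 3])
        assert f(10.0) == pytest.approx(f(3.0))


class TestIsdm:
    def test_flat_profile_equals_D_over_L(self):
        grid = np.linspace(0.0, 60.0, 121)
        G = FreeEnergyProfile(grid, np.zeros_like(grid))
        D = DiffusivityProfile(grid, np.full_like(grid, 60.0))
        est = isdm_permeability(G, D, 0.0, 60.0, n_resamples=0)
        assert est.P == pytest.approx(10.0, rel=1e-6)   # 1 Å/ns

    def test_anchoring_gauge(self):
        """A constant shift c scales P by exp(−βc); the min-zero anchor
        removes the shift, so profiles differing by a constant give equal P."""
        grid = np.linspace(-10.0, 10.0, 81)
        g = 2.0 * np.exp(-grid**2 / 8.0)
        G1 = FreeEnergyProfile(grid, g)
        G2 = FreeEnergyProfile(grid, g + 7.3)    # re-anchored internally
        D = DiffusivityProfile(grid, np.full_like(grid, 50.0))
        p1 = isdm_permeability(G1, D, -10, 10, n_resamples=0).P
        p2 = isdm_permeability(G2, D, -10, 10, n_resamples=0).P
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_square_barrier_matches_hand_quadrature(self):
        """5 kcal/mol over 10 Å, D = 50 Å²/ns, 60 Å span."""
        eps = 1e-3
        grid = np.sort(np.concatenate([
            np.linspace(-30, 30, 241),
            [-5 - eps, -5 + eps, 5 - eps, 5 + eps]]))
        g = np.where(np.abs(grid) < 5.0, 5.0, 0.0)
        G = FreeEnergyProfile(grid, g)
        D = DiffusivityProfile(grid, np.full_like(grid, 50.0))
        est = isdm_permeability(G, D, -30.0, 30.0, n_resamples=0,
                                smooth=False)
        integral = 50.0 / 50.0 + 10.0 * np.exp(BETA * 5.0) / 50.0
        assert est.P == pytest.approx(10.0 / integral, rel=0.01)

    def test_bounds_outside_profile_rejected(self):
        grid = np.linspace(0.0, 10.0, 21)
        G = FreeEnergyProfile(grid, np.zeros_like(grid))
        D = DiffusivityProfile(grid, np.full_like(grid, 50.0))
        with pytest.raises(ValueError, match="bounds"):
            isdm_permeability(G, D, -5.0, 10.0, n_resamples=0)

    def test_pipeline_recovers_generating_permeability(
            self, double_well_windows):
        """windows on stated (G, D) → WHAM + diffusivity + ISDM within 30%
        of the direct quadrature of the generating profiles."""
        _, wins = double_well_windows
        res = UmbrellaPermeability(wins, bounds=(-6.0, 6.0),
                                   n_bootstrap=0).fit()
        lo, hi = res.bounds
        xs = np.linspace(lo, hi, 4001)
        gmin = double_well(xs).min()
        integrand = lambda x: np.exp(BETA * (double_well(x) - gmin)) / 70.0
        val, _ = integrate.quad(integrand, lo, hi, limit=400)
        p_true = 10.0 / val
        assert res.P == pytest.approx(p_true, rel=0.30)


class TestEffectivePermeability:
    @pytest.mark.parametrize("p_h, p_t, expected",
                             [(23.9, 13.5, 3.7), (33.7, 13.3, 5.0)])
    def test_mixed_pore_tile(self, p_h, p_t, expected):
        est = effective_permeability(PoreSet(P_H=p_h, P_T=p_t, n_H=3,
                                             r_cyl=15.0, A_tile=16166.0))
        assert round(est.P, 1) == expected

    def test_zero_pores_zero_permeability(self):
        est = effective_permeability(PoreSet(P_H=0.0, P_T=0.0))
        assert est.P == 0.0

    def test_area_fraction(self):
        assert PoreSet(P_H=1, P_T=1).area_fraction == \
            pytest.approx(0.0437, abs=5e-5)


def _cylinder_traj(z_samples, axis=np.array([0.0, 0.0, 1.0]), r_max=5.0,
                   seed=0, shell_r=30.0):
    """Particles inside a pore-axis cylinder at given axial offsets."""
    rng = np.random.default_rng(seed)
    n = len(z_samples)
    rr = r_max * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([rr * np.cos(th), rr * np.sin(th),
                           shell_r + np.asarray(z_samples)])
    ps = ParticleSet(particle_id=np.arange(n),
                     species=np.full(n, "G3P", dtype=object),
                     role=np.full(n, "metabolite", dtype=object),
                     complex_id=np.full(n, -1),
                     is_calpha=np.zeros(n, bool), coordinates=pos)
    traj = Trajectory(np.array([0.0]), pos[None], np.zeros(3), True, ps)
    shell = ShellGeometry(center=np.zeros(3), R_mid=shell_r,
                          R_in=shell_r - 10, R_out=shell_r + 10,
                          A=4 * np.pi * shell_r**2,
                          pores=[(axis, 5.0)])
    return traj, shell


class TestBoltzmannInversion:
    def test_uniform_occupancy_is_flat(self):
        rng = np.random.default_rng(3)
        traj, shell = _cylinder_traj(rng.uniform(-10, 10, 200_000))
        prof = boltzmann_inversion(traj, shell, cylinder_radius=15.0,
                                   species=("G3P",), bin_width=1.0)
        assert np.all(prof.G <= 2 * prof.stderr * 3 + 0.05)

    def test_gaussian_occupancy_inverts_to_quadratic(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0.0, np.sqrt(0.5), 400_000)   # p ∝ exp(−z²)
        traj, shell = _cylinder_traj(z)
        prof = boltzmann_inversion(traj, shell, cylinder_radius=15.0,
                                   species=("G3P",), bin_width=0.25)
        keep = np.abs(prof.grid) < 1.5
        expected = KBT * prof.grid[keep] ** 2
        expected -= expected.min()
        np.testing.assert_allclose(prof.G[keep], expected, atol=0.05)

    def test_empty_selection_is_an_error(self):
        traj, shell = _cylinder_traj(np.zeros(10))
        with pytest.raises(ValueError, match="species"):
            boltzmann_inversion(traj, shell, species=("DHAP",))


class TestPmf2d:
    def test_uniform_density_is_flat_after_reweighting(self):
        rng = np.random.default_rng(9)
        n = 400_000
        pos = rng.uniform(-10, 10, (n, 3))
        pos[:, 2] += 30.0
        ps = ParticleSet(particle_id=np.arange(n),
                         species=np.full(n, "G3P", dtype=object),
                         role=np.full(n, "metabolite", dtype=object),
                         complex_id=np.full(n, -1),
                         is_calpha=np.zeros(n, bool), coordinates=pos)
        traj = Trajectory(np.array([0.0]), pos[None], np.zeros(3), True, ps)
        shell = ShellGeometry(center=np.zeros(3), R_mid=30.0, R_in=20.0,
                              R_out=40.0, A=4 * np.pi * 900,
                              pores=[(np.array([0.0, 0, 1.0]), 5.0)])
        _, _, G = pmf_2d(traj, shell, species=("G3P",), z_bins=8, r_bins=6,
                         z_range=(-8, 8), r_max=8.0)
        vals = G[np.isfinite(G)]
        assert vals.max() - vals.min() < 0.1

    def test_single_occupied_bin(self):
        pos = np.tile([[1.0, 0.0, 31.0]], (50, 1))
        ps = ParticleSet(particle_id=np.arange(50),
                         species=np.full(50, "G3P", dtype=object),
                         role=np.full(50, "metabolite", dtype=object),
                         complex_id=np.full(50, -1),
                         is_calpha=np.zeros(50, bool), coordinates=pos)
        traj = Trajectory(np.array([0.0]), pos[None], np.zeros(3), True, ps)
        shell = ShellGeometry(center=np.zeros(3), R_mid=30.0, R_in=20.0,
                              R_out=40.0, A=4 * np.pi * 900,
                              pores=[(np.array([0.0, 0, 1.0]), 5.0)])
        _, _, G = pmf_2d(traj, shell, species=("G3P",), z_bins=4, r_bins=4,
                         z_range=(-2, 2), r_max=4.0)
        assert np.nansum(G == 0.0) == 1
        assert np.isnan(G).sum() == G.size - 1


class TestWindowFileIO:
    def test_round_trip(self, tmp_path):
        w = UmbrellaWindow(3.5, 5.0, np.linspace(3, 4, 100), 0.5)
        path = tmp_path / "w.txt"
        write_window_file(w, path)
        back = read_window_file(path)
        assert back.center == w.center and back.k == w.k
        np.testing.assert_allclose(back.samples, w.samples, atol=1e-5)
        assert back.sample_interval == pytest.approx(0.5)
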