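"""RDFs, correlation length/time fits, structure factors, density maps."""

import numpy as np
import pytest
from scipy import integrate, optimize

import nanodomain as nd
from nanodomain import (rdf2d, fit_correlation_length, fit_linear_decay,
                        structure_factor, structure_factor_fft,
                        density_time_correlation, density_map, map_contrast,
                        RadialProfile)
from nanodomain.synthetic import (LatticeGasParams, generate_lattice_gas,
                                  generate_brownian_trajectory)


class TestRDF:
    def test_poisson_points_flat_within_counting_noise(self):
        rng = np.random.default_rng(1)
        box = (40.0, 40.0)
        xy = rng.uniform(0, box, (2000, 2))
        prof = rdf2d(xy, box, bin_width=0.25)
        sig = prof.sigma()
        good = np.isfinite(sig) & (prof.r > prof.bin_width)
        # per-bin counting-noise envelope (sigma is approximate: shared
        # points correlate neighbouring bins slightly)
        assert np.all(np.abs(prof.g[good] - 1.0) < 4.5 * sig[good])
        # area-weighted mean of g over the profile support is ~1
        ring = prof.r
        assert np.average(prof.g[good], weights=ring[good]) == \
            pytest.approx(1.0, abs=0.01)

    def test_two_points_single_bin_hand_normalization(self):
        box = (50.0, 50.0)
        d = 7.3
        xy = np.array([[10.0, 10.0], [10.0 + d, 10.0]])
        prof = rdf2d(xy, box, bin_width=0.2)
        hot = np.flatnonzero(prof.counts)
        assert len(hot) == 1
        assert prof.r[hot[0]] == pytest.approx(d, abs=0.2)
        # 2 ordered pairs / (n * (n-1)/A * ring area)
        lo = prof.r[hot[0]] - 0.1
        ring = np.pi * ((lo + 0.2) ** 2 - lo ** 2)
        expected = 2.0 / (2 * (1 / (50.0 * 50.0)) * ring)
        assert prof.g[hot[0]] == pytest.approx(expected, rel=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        xy = np.random.default_rng(0).uniform(0, 10, (50, 2))
        with pytest.raises(ValueError):
            rdf2d(xy, (10.0, 10.0), r_max=6.0)

    def test_demixed_frame_long_range_linear_decay(self):
        frame = generate_lattice_gas(LatticeGasParams(
            lattice_side=28, coupling=1.1, sweeps=3000, seed=2))
        xy = frame.upper.xy[frame.upper.species == "unsat"]
        prof = rdf2d(xy, frame.box, bin_width=0.25,
                     reference_xy=frame.upper.xy)
        lin = fit_linear_decay(prof)
        assert lin["b1"] < -0.02


class TestCorrelationLengthFit:
    def _synthetic_profile(self, xi, noise, seed=0, a0=0.8, a1=1.0):
        rng = np.random.default_rng(seed)
        r = np.arange(0.05, 12.0, 0.1)
        g = a0 * np.exp(-r / xi) + a1 + rng.normal(0, noise, len(r))
        return RadialProfile(r=r, g=g, counts=np.full(len(r), 1e4),
                             bin_width=0.1)

    @pytest.mark.parametrize("xi", [0.8, 2.0, 4.0])
    def test_parameter_recovery(self, xi):
        prof = self._synthetic_profile(xi, noise=0.01, seed=3)
        fit = fit_correlation_length(prof, fit_range=(0.0, None))
        assert fit.success
        assert fit.xi == pytest.approx(xi, rel=0.05)

    def test_constant_profile_refused(self):
        prof = self._synthetic_profile(2.0, noise=0.01, seed=4, a0=0.0)
        fit = fit_correlation_length(prof, fit_range=(0.0, None))
        assert not fit.success

    def test_estimator_unbiased_at_moderate_noise(self):
        xis = []
        for seed in range(100):
            prof = self._synthetic_profile(2.0, noise=0.05, seed=seed)
            fit = fit_correlation_length(prof, fit_range=(0.0, None))
            if fit.success:
                xis.append(fit.xi)
        assert len(xis) > 90
        assert abs(np.mean(xis) - 2.0) / 2.0 < 0.05

    def test_subcritical_coupling_increases_xi(self):
        means = []
        for coupling in (0.3, 0.55):
            vals = []
            for seed in range(5):
                frame = generate_lattice_gas(LatticeGasParams(
                    lattice_side=28, coupling=coupling, sweeps=1500,
                    seed=seed))
                xy = frame.upper.xy[frame.upper.species == "unsat"]
                prof = rdf2d(xy, frame.box, bin_width=0.2,
                             reference_xy=frame.upper.xy)
                fit = fit_correlation_length(prof)
                if fit.success:
                    vals.append(fit.xi)
            means.append(np.mean(vals))
        assert means[0] < means[1]

    def test_too_few_bins_rejected(self):
        prof = RadialProfile(r=np.array([1.0, 2, 3]), g=np.ones(3),
                             counts=np.ones(3), bin_width=1.0)
        with pytest.raises(ValueError):
            fit_correlation_length(prof, fit_range=(0.0, None))


class TestStructureFactor:
    def test_poisson_points_ideal_gas_level(self):
        rng = np.random.default_rng(5)
        box = (40.0, 40.0)
        xy = rng.uniform(0, box, (2000, 2))
        sp = structure_factor(xy, box, q_max=3.0)
        assert np.mean(sp.s) == pytest.approx(1.0, abs=0.05)

    def test_single_row_bragg_peak_at_exact_wavevector(self):
        d, n = 2.0, 10
        xy = np.column_stack([np.arange(n) * d, np.full(n, 5.0)])
        sp = structure_factor(xy, (n * d, 10.0), q_max=4.0)
        i = int(np.argmin(np.abs(sp.qx - 2 * np.pi / d)))
        j = int(np.argmin(np.abs(sp.qy)))
        assert sp.s2d[i, j] == pytest.approx(n, rel=1e-9)

    def test_striped_configuration_radial_peak_at_stripe_period(self):
        """Points filling alternating stripes of period P give the dominant
        radial peak at q = 2 pi / P."""
        rng = np.random.default_rng(6)
        box = (40.0, 40.0)
        period = 10.0
        xy = rng.uniform(0, box, (4000, 2))
        keep = (np.mod(xy[:, 0], period) < period / 2)
        sp = structure_factor(xy[keep], box, q_max=2.5)
        q_peak, _ = sp.peak(q_min=0.3)
        assert q_peak == pytest.approx(2 * np.pi / period, abs=sp.q_resolution)

    def test_direct_sum_equals_fft_on_commensurate_grid(self):
        rng = np.random.default_rng(7)
        grid_n, box = 32, (16.0, 16.0)
        ij = rng.integers(0, grid_n, size=(150, 2))
        xy = ij * (box[0] / grid_n)
        sp = structure_factor(xy, box, q_max=2.0)
        counts = np.zeros((grid_n, grid_n))
        np.add.at(counts, (ij[:, 0], ij[:, 1]), 1)
        s_fft = structure_factor_fft(counts, box)
        mx = (len(sp.qx) - 1) // 2
        for i, m1 in enumerate(range(-mx, mx + 1)):
            for j, m2 in enumerate(range(-mx, mx + 1)):
                assert abs(sp.s2d[i, j] - s_fft[m1 % grid_n, m2 % grid_n]) \
                    < 1e-8


def exact_cell_autocorrelation(lags, d_coeff, cell):
    """Closed-form local-density autocorrelation for free 2D diffusion:
    product of per-axis triangular-window Gaussian integrals."""
    def c1(t):
        if t <= 0:
            return 1.0
        s2 = 2 * d_coeff * t
        f = (lambda u: (1 - abs(u) / cell)
             * np.exp(-u * u / (2 * s2)) / np.sqrt(2 * np.pi * s2))
        val, _ = integrate.quad(f, -cell, cell)
        return val
    return np.array([c1(t) ** 2 for t in lags])


class TestCorrelationTime:
    def test_static_frames_flagged_no_decay(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 20, (300, 2))
        tc = density_time_correlation([xy] * 12, (20.0, 20.0), dt=1.0)
        assert tc.status in ("static", "no_decay")
        assert np.isinf(tc.tau)
        assert np.all(tc.c == pytest.approx(1.0))

    def test_iid_frames_flagged_unresolved(self):
        rng = np.random.default_rng(9)
        frames = [rng.uniform(0, 20, (300, 2)) for _ in range(12)]
        tc = density_time_correlation(frames, (20.0, 20.0), dt=1.0)
        assert tc.status == "unresolved"
        assert np.all(np.abs(tc.c[1:]) < 0.2)

    def test_brownian_tau_matches_exact_diffusion_oracle(self):
        """Same exponential-fit protocol applied to the exact Gaussian
        autocorrelation is the oracle; simulated tau agrees within 25%."""
        d_nm = 0.025     # nm^2/ns; cell 1 nm
        lags = np.arange(1, 10) * 1.0
        c_true = exact_cell_autocorrelation(lags, d_nm, 1.0)
        popt, _ = optimize.curve_fit(lambda t, tau: np.exp(-t / tau),
                                     lags, c_true, p0=[5.0])
        tau_oracle = popt[0]
        taus = []
        for seed in range(10):
            traj = generate_brownian_trajectory(
                {"a": 400}, {"a": d_nm * 1e-5}, dt_ns=1.0, n_frames=600,
                box=(20, 20), seed=seed)
            tc = density_time_correlation(list(traj.wrapped), (20.0, 20.0),
                                          dt=1.0, grid=(20, 20), n_lags=9)
            assert tc.status == "ok"
            taus.append(tc.tau)
        assert np.mean(taus) == pytest.approx(tau_oracle, rel=0.25)

    def test_tau_scales_inversely_with_diffusion(self):
        def mean_tau(d_nm):
            taus = []
            for seed in range(5):
                traj = generate_brownian_trajectory(
                    {"a": 400}, {"a": d_nm * 1e-5}, dt_ns=1.0, n_frames=600,
                    box=(20, 20), seed=seed)
                tc = density_time_correlation(list(traj.wrapped),
                                              (20.0, 20.0), dt=1.0)
                taus.append(tc.tau)
            return np.mean(taus)
        assert mean_tau(0.025) / mean_tau(0.05) == pytest.approx(2.0, rel=0.3)

    def test_insufficient_frames_rejected(self):
        with pytest.raises(ValueError):
            density_time_correlation([np.zeros((5, 2))] * 5, (10.0, 10.0),
                                     dt=1.0, n_lags=9)


class TestDensityMaps:
    def test_uniform_static_points_flat_map(self):
        # square lattice commensurate with the map grid: exactly 4 points
        # per 2x2 nm cell
        i, j = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        pos = np.column_stack([i.ravel() + 0.5, j.ravel() + 0.5]).astype(float)
        maps = density_map([pos] * 4, (20.0, 20.0), dt=1.0, window_frames=4,
                           grid_spacing=2.0)
        assert len(maps) == 1
        dens = maps[0].density
        assert np.all(dens == dens.flat[0])

    def test_grid_integral_equals_mean_count(self):
        rng = np.random.default_rng(10)
        frames = [rng.uniform(0, 20, (317, 2)) for _ in range(6)]
        maps = density_map(frames, (20.0, 20.0), dt=1.0, window_frames=3)
        for m in maps:
            assert m.integral() == pytest.approx(317, rel=1e-6)

    def test_persistent_demixed_state_keeps_contrast(self):
        from nanodomain.synthetic import generate_lattice_gas_trajectory
        frames = generate_lattice_gas_trajectory(
            LatticeGasParams(lattice_side=24, coupling=1.1, sweeps=2500,
                             seed=11), n_frames=8, sweeps_per_frame=60)
        pts = [f.upper.xy[f.upper.species == "sat"] for f in frames]
        box = frames[0].box
        short = density_map(pts, box, 1.0, window_frames=1, grid_spacing=2.0)
        long_ = density_map(pts, box, 1.0, window_frames=8, grid_spacing=2.0)
        ratio = map_contrast(long_[0]) / np.mean([map_contrast(m)
                                                  for m in short])
        assert ratio > 0.8

    def test_mixed_state_contrast_decays_with_window(self):
        from nanodomain.synthetic import generate_lattice_gas_trajectory
        frames = generate_lattice_gas_trajectory(
            LatticeGasParams(lattice_side=24, coupling=0.2, sweeps=400,
                             seed=12), n_frames=8, sweeps_per_frame=120)
        pts = [f.upper.xy[f.upper.species == "sat"] for f in frames]
        box = frames[0].box
        contrasts = []
        for w in (1, 4, 8):
            maps = density_map(pts, box, 1.0, window_frames=w,
                               grid_spacing=2.0)
            contrasts.append(np.mean([map_contrast(m) for m in maps]))
        assert contrasts[0] > contrasts[1] > contrasts[2]

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            density_map([np.zeros((5, 2))] * 3, (10.0, 10.0), dt=1.0,
                        window_frames=5)
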