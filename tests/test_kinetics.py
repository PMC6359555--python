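import numpy as np
import pytest

from pathmd.datasets import dialanine_table
from pathmd.kinetics_analysis import (
    acceleration_factor,
    arrhenius_fit,
    dipole_statistics,
    fit_multiexponential,
    free_energy_landscape,
    transition_times,
)
from pathmd.model_systems import double_well_potential
from pathmd.units import KB, R_GAS


class TestTransitionTimes:
    def test_square_wave_waiting_time(self):
        T = 10.0
        t = np.arange(0.0, 120.0, 0.1)
        v = np.where((t // T) % 2 == 0, -1.0, 1.0)
        res = transition_times(t, v, threshold=0.0, dwell_time=1.0)
        assert res.tau == pytest.approx(T, rel=0.02)

    def test_single_crossing_from_start(self):
        t = np.arange(0.0, 20.0, 0.1)
        v = np.where(t < 5.0, -1.0, 1.0)
        res = transition_times(t, v, dwell_time=1.0)
        assert res.n_events == 1
        assert res.tau == pytest.approx(5.0)

    def test_no_transition_is_explicit(self):
        t = np.arange(0.0, 10.0, 0.1)
        res = transition_times(t, -np.ones_like(t))
        assert res.n_events == 0
        assert res.tau is None and res.nu is None

    def test_short_spike_not_double_counted(self):
        t = np.arange(0.0, 30.0, 0.1)
        v = -np.ones_like(t)
        v[(t >= 10.0) & (t < 10.3)] = 1.0  # 0.3 ps noise spike
        v[t >= 20.0] = 1.0
        res = transition_times(t, v, dwell_time=1.0)
        assert res.n_events == 1
        assert res.crossing_times[0] == pytest.approx(20.0)

    def test_telegraph_process_rate_recovery(self, rng):
        """A two-state Markov process with known switching rate is
        recovered within 2 standard errors over ~1e3 events."""
        rate = 0.2  # per ps
        waits = rng.exponential(1.0 / rate, size=1000)
        times = np.concatenate([[0.0], np.cumsum(waits)])
        t = np.arange(0.0, times[-1], 0.05)
        state = (np.searchsorted(times, t, side="right") - 1) % 2
        res = transition_times(t, state.astype(float), threshold=0.5, dwell_time=0.0)
        se = (1.0 / rate) / np.sqrt(res.n_events)
        assert abs(res.tau - 1.0 / rate) < 2 * se


class TestArrhenius:
    def test_published_dialanine_tables(self):
        """The three bundled transition-time tables reproduce the
        published activation energies within 2%."""
        for proto, ea_ref in [("md", 21.05), ("path_sampling", 18.77),
                              ("principal_components", 9.2)]:
            T, tau = dialanine_table(proto)
            fit = arrhenius_fit(T, tau)
            assert fit.ea == pytest.approx(ea_ref, rel=0.02)

    def test_exact_inverse_of_generated_data(self):
        Ea, lnA = 10.0, 3.0
        T = np.array([280.0, 320.0, 360.0, 400.0])
        tau = 1.0 / np.exp(lnA - Ea / (R_GAS * T))
        fit = arrhenius_fit(T, tau)
        assert fit.ea == pytest.approx(Ea, rel=1e-12)
        assert fit.ln_a == pytest.approx(lnA, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit([300.0, 300.0], [10.0, 12.0])

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit([300.0, 350.0], [10.0, -1.0])


class TestAcceleration:
    def test_equal_times_give_unity(self):
        assert acceleration_factor(5.0, 5.0).rho == 1.0

    def test_published_table_ratio(self):
        est = acceleration_factor(42696.0, 3873.0)
        assert est.rho == pytest.approx(11.02, abs=0.01)

    def test_halved_time_doubles_rate(self):
        est = acceleration_factor(10.0, 5.0)
        assert est.rho == pytest.approx(2.0)
        assert est.ln_rho == pytest.approx(np.log(2.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            acceleration_factor(0.0, 1.0)


class TestFreeEnergyLandscape:
    def test_uniform_histogram_is_flat(self, rng):
        x = rng.uniform(0, 1, size=200_000)
        grid = free_energy_landscape(x, 10, 300.0)
        occ = ~np.isnan(grid.delta_f)
        assert np.nanmax(grid.delta_f[occ]) < 0.1

    def test_probability_ratio_e_gives_one_kbt(self):
        x = np.concatenate([np.zeros(27_183), np.ones(10_000)])
        grid = free_energy_landscape(x, [-0.5, 0.5, 1.5], 300.0)
        assert grid.delta_f[1] - grid.delta_f[0] == pytest.approx(
            np.log(2.7183), rel=1e-3
        )

    def test_invariant_under_sample_duplication(self, rng):
        x = rng.normal(size=5000)
        edges = np.linspace(-3, 3, 21)
        a = free_energy_landscape(x, edges, 300.0)
        b = free_energy_landscape(np.concatenate([x, x]), edges, 300.0)
        occ = ~np.isnan(a.delta_f)
        assert np.allclose(a.delta_f[occ], b.delta_f[occ])

    def test_min_reference_convention(self, rng):
        x = rng.normal(size=10_000)
        grid = free_energy_landscape(x, 15, 300.0, ref="min")
        assert np.nanmax(grid.delta_f) == pytest.approx(0.0)
        assert np.nanmin(grid.delta_f) < 0.0

    def test_degenerate_single_bin_flagged(self):
        grid = free_energy_landscape(np.zeros(100), 5, 300.0)
        assert grid.degenerate

    def test_boltzmann_samples_recover_double_well_profile(self, rng):
        """Rejection-sampled Boltzmann draws from the quartic double well
        give Delta F within 3 SE of V(x)/kBT per bin."""
        a, b, T = 5.0, 0.5, 300.0
        beta = 1.0 / (KB * T)
        n = 1_000_000
        x = rng.uniform(-1.0, 1.0, size=n)
        e = a * ((x / b) ** 2 - 1.0) ** 2
        keep = rng.uniform(size=n) < np.exp(-beta * e)
        x = x[keep]
        edges = np.linspace(-0.9, 0.9, 25)
        grid = free_energy_landscape(x, edges, T)
        # analytic bin probabilities by fine quadrature of the Boltzmann
        # weight (the oracle must integrate over the bin, not use its
        # center, or the steep edge bins are misrepresented)
        p_ref = np.empty(len(edges) - 1)
        for j in range(len(p_ref)):
            xs = np.linspace(edges[j], edges[j + 1], 200)
            p_ref[j] = np.trapezoid(np.exp(-beta * a * ((xs / b) ** 2 - 1) ** 2), xs)
        p_ref /= p_ref.sum()
        f_ref = -np.log(p_ref / p_ref.max())
        occ = grid.counts > 200
        dev = grid.delta_f[occ] - f_ref[occ]
        # per-bin multinomial standard error of -ln p
        se = 1.0 / np.sqrt(grid.counts[occ])
        assert np.all(np.abs(dev - dev.mean()) < 3 * np.maximum(se, 0.01))


class TestMultiExponential:
    def test_noiseless_single_mode_recovered_exactly(self):
        t = np.linspace(0, 10, 200)
        y = 1.0 * np.exp(-0.5 * t)
        fit = fit_multiexponential(t, y, 1)
        assert fit.rates[0] == pytest.approx(0.5, abs=1e-8)
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_mode_noisy_recovery_within_5_percent(self):
        """A = 0.7/0.3, k = 1.0/0.1 with 1% noise, 20 seeds."""
        t = np.linspace(0, 30, 400)
        clean = 0.7 * np.exp(-1.0 * t) + 0.3 * np.exp(-0.1 * t)
        for seed in range(20):
            noise_rng = np.random.default_rng(1000 + seed)
            y = clean + 0.01 * noise_rng.standard_normal(t.shape)
            fit = fit_multiexponential(t, y, 2, seed=seed)
            assert fit.rates[0] == pytest.approx(1.0, rel=0.05)
            assert fit.rates[1] == pytest.approx(0.1, rel=0.05)
            assert fit.amplitudes[0] == pytest.approx(0.7, rel=0.05)
            assert fit.amplitudes[1] == pytest.approx(0.3, rel=0.05)

    def test_constant_signal_limits_to_zero_rate(self):
        t = np.linspace(0, 5, 50)
        fit = fit_multiexponential(t, np.full_like(t, 0.8), 1)
        assert fit.rates[0] < 1e-6
        assert fit.amplitudes[0] == pytest.approx(0.8, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_multiexponential([0.0, 1.0], [1.0, np.nan], 1)
        with pytest.raises(ValueError):
            fit_multiexponential([0.0, 1.0], [1.0, 0.5], 0)


class TestDipoleStatistics:
    def test_constant_dipole(self):
        M = np.tile([0.1, 0.2, 0.3], (50, 1))
        acf, eps0 = dipole_statistics(M, volume=10.0, temperature=300.0)
        assert np.all(acf == 1.0)
        assert eps0 == 1.0

    def test_cosine_dipole_acf_envelope(self):
        w = 2 * np.pi / 10.0
        t = np.arange(0.0, 200.0, 0.1)
        M = np.zeros((len(t), 3))
        M[:, 2] = np.cos(w * t)
        acf, _ = dipole_statistics(M, 10.0, 300.0)
        lags = np.arange(60)
        assert np.allclose(acf[:60], np.cos(w * 0.1 * lags), atol=0.05)

    def test_gaussian_fluctuations_match_closed_form(self, rng):
        var = 0.04  # (e nm)^2 per component
        n = 40_000
        M = rng.normal(scale=np.sqrt(var), size=(n, 3))
        _, eps0 = dipole_statistics(M, volume=15.0, temperature=300.0)
        e, eps_0, kb = 1.602176634e-19, 8.8541878128e-12, 1.380649e-23
        expected = 1.0 + 3 * var * (e * 1e-9) ** 2 / (
            3 * eps_0 * 15.0e-27 * kb * 300.0
        )
        se_rel = np.sqrt(2.0 / (3 * n))
        assert eps0 == pytest.approx(expected, rel=4 * se_rel)
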