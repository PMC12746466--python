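"""Kinetic Monte Carlo cooling: step probabilities, acceptance conventions,
detailed balance in the harmonic limit, and relaxation phenomenology."""

import math

import numpy as np
import pytest

from anhcascade import kmc_cooling as kmc
from anhcascade.constants import C_CM_PER_FS, KB_CM1_PER_K
from anhcascade.state_density import brute_force_states
from anhcascade.synthetic_fixtures import make_harmonic_system, rng_from_seed
from anhcascade.vib_model import total_energy


class TestStepProbabilities:
    def test_zero_occupation_cannot_step_down(self, one_mode_harmonic):
        params = kmc.KmcParams(t_max=0.0)
        p_down, _ = kmc.step_probabilities(one_mode_harmonic, np.array([0]), params)
        assert p_down[0] == 0.0

    def test_hand_checked_down_probability(self, one_mode_harmonic):
        # q=0.1, nu=1000, dt=5 fs, n=1 -> 0.1 * 1000 * c * 5 = 0.0149896
        params = kmc.KmcParams(q=0.1, dt=5.0, t_max=0.0)
        p_down, _ = kmc.step_probabilities(one_mode_harmonic, np.array([1]), params)
        assert p_down[0] == pytest.approx(0.1 * 1000.0 * C_CM_PER_FS * 5.0, rel=1e-12)
        assert p_down[0] == pytest.approx(0.014990, abs=1e-6)

    def test_hand_checked_up_probability(self, one_mode_harmonic):
        params = kmc.KmcParams(q=0.1, dt=5.0, T_bath=300.0, t_max=0.0)
        _, p_up = kmc.step_probabilities(one_mode_harmonic, np.array([0]), params)
        kt = KB_CM1_PER_K * 300.0
        expected = 0.1 * 1000.0 * C_CM_PER_FS * 5.0 * math.exp(-1000.0 / kt)
        assert p_up[0] == pytest.approx(expected, rel=1e-12)
        assert p_up[0] == pytest.approx(1.24e-4, rel=0.01)

    def test_detailed_balance_ratio_is_boltzmann(self, one_mode_harmonic):
        """up(n -> n+1) / down(n+1 -> n) = e^{-nu/kT}: the proposal rates
        alone equilibrate a harmonic mode at the bath temperature."""
        params = kmc.KmcParams(t_max=0.0)
        kt = KB_CM1_PER_K * params.T_bath
        for n in range(4):
            _, p_up = kmc.step_probabilities(
                one_mode_harmonic, np.array([n]), params
            )
            p_down, _ = kmc.step_probabilities(
                one_mode_harmonic, np.array([n + 1]), params
            )
            assert p_up[0] / p_down[0] == pytest.approx(
                math.exp(-1000.0 / kt), rel=1e-12
            )

    def test_oversized_dt_clipped_with_warning(self, one_mode_harmonic):
        params = kmc.KmcParams(q=100.0, dt=1000.0, t_max=0.0)
        with pytest.warns(RuntimeWarning):
            p_down, p_up = kmc.step_probabilities(
                one_mode_harmonic, np.array([5]), params
            )
        assert np.all(p_down + p_up <= 1.0)

    def test_per_mode_rate_override(self):
        system = make_harmonic_system([500.0, 1000.0])
        params = kmc.KmcParams(q_i=np.array([0.2, 0.05]), t_max=0.0)
        p_down, _ = kmc.step_probabilities(system, np.array([1, 1]), params)
        assert p_down[0] == pytest.approx(0.2 * 500.0 * C_CM_PER_FS * 5.0)
        assert p_down[1] == pytest.approx(0.05 * 1000.0 * C_CM_PER_FS * 5.0)


class TestAcceptance:
    def test_as_printed_down_move_is_penalised(self, rng):
        """The printed rule e^{-(E-E_prop)/kT} accepts a harmonic down-move
        (E - E_prop = nu) with probability e^{-nu/kT}."""
        kt = KB_CM1_PER_K * 300.0
        nu = 500.0
        accepts = sum(
            kmc._accept(-nu, kt, "as_printed", rng) for _ in range(20_000)
        )
        assert accepts / 20_000 == pytest.approx(math.exp(-nu / kt), rel=0.1)

    def test_as_printed_equal_energy_always_accepts(self, rng):
        kt = KB_CM1_PER_K * 300.0
        assert all(kmc._accept(0.0, kt, "as_printed", rng) for _ in range(100))

    def test_metropolis_downhill_always_accepts(self, rng):
        kt = KB_CM1_PER_K * 300.0
        assert all(kmc._accept(-50.0, kt, "metropolis", rng) for _ in range(100))

    def test_none_always_accepts(self, rng):
        kt = KB_CM1_PER_K * 300.0
        assert all(kmc._accept(1e6, kt, "none", rng) for _ in range(100))


class TestKmcStep:
    def test_no_proposals_leaves_config_unchanged(self, one_mode_harmonic):
        # with n = 0 and a cold bath the proposal probabilities are tiny
        params = kmc.KmcParams(T_bath=1.0, acceptance_mode="none", t_max=0.0)
        rng = rng_from_seed(0)
        n = kmc.kmc_step(one_mode_harmonic, np.array([0]), params, rng)
        assert n[0] == 0

    def test_single_quantum_energy_delta_matches_total_energy(self, toy3):
        cfg = np.array([2, 1, 0])
        for i in range(3):
            for sign in (+1, -1):
                if sign == -1 and cfg[i] == 0:
                    continue
                delta = kmc._single_mode_delta(toy3, cfg, i, sign)
                moved = cfg.copy()
                moved[i] += sign
                expected = total_energy(toy3, moved) - total_energy(toy3, cfg)
                assert delta == pytest.approx(expected, abs=1e-9)

    def test_occupations_never_negative(self, toy3):
        params = kmc.KmcParams(
            q=1.0, dt=20.0, acceptance_mode="none", t_max=0.0, T_bath=600.0
        )
        rng = rng_from_seed(4)
        n = np.array([3, 2, 1])
        for _ in range(500):
            n = kmc.kmc_step(toy3, n, params, rng)
            assert np.all(n >= 0)


class TestTrajectories:
    def test_zero_tmax_single_row(self, one_mode_harmonic):
        params = kmc.KmcParams(t_max=0.0, spectral_window=(900.0, 1100.0),
                               spectral_bin=2.0)
        out = np.zeros((1, 100))
        traj = kmc.run_trajectory(
            one_mode_harmonic, np.array([0]), params, rng_from_seed(0),
            spectral_out=out,
        )
        assert traj.times.tolist() == [0.0]
        # one fundamental line at 1000 -> bin (1000-900)/2 = 50
        assert out[0].sum() == pytest.approx(1.0)
        assert out[0][50] == pytest.approx(1.0)

    def test_harmonic_bose_einstein_occupation(self):
        """Long single-mode run with acceptance 'none' time-averages to the
        Bose-Einstein occupation 1/(e^{nu/kT} - 1) within 3 sigma."""
        nu = 500.0
        system = make_harmonic_system([nu])
        params = kmc.KmcParams(
            q=1.0, dt=5.0, acceptance_mode="none", T_bath=300.0, t_max=0.0
        )
        rng = rng_from_seed(42)
        kt = KB_CM1_PER_K * 300.0
        target = 1.0 / (math.exp(nu / kt) - 1.0)
        n = np.array([0])
        n_steps = 200_000
        burn = 2_000
        batch_means = []
        acc = 0
        batch = (n_steps - burn) // 50
        count = 0
        for s in range(n_steps):
            n = kmc.kmc_step(system, n, params, rng)
            if s >= burn:
                acc += n[0]
                count += 1
                if count == batch:
                    batch_means.append(acc / count)
                    acc = count = 0
        mean = np.mean(batch_means)
        sem = np.std(batch_means, ddof=1) / math.sqrt(len(batch_means))
        assert abs(mean - target) < 3 * sem + 1e-4
        assert mean == pytest.approx(0.1001, abs=0.02)

    def test_hot_ensemble_cools_to_thermal_mean(self, toy3):
        """Ensemble-mean energy decays from a hot start toward the exact
        300 K canonical mean of the enumerated states."""
        params = kmc.KmcParams(
            q=1.0, dt=5.0, t_max=3000.0, acceptance_mode="none",
            n_trajectories=40,
        )
        hot = np.array([4, 3, 2])
        times, e_mean = kmc.ensemble_energy(
            toy3, [hot], params, rng_from_seed(9)
        )
        kt = KB_CM1_PER_K * 300.0
        states = brute_force_states(toy3, 8000.0)
        weights = np.array([math.exp(-e / kt) for _, e in states])
        e_thermal = float(
            sum(w * e for (_, e), w in zip(states, weights)) / weights.sum()
        )
        assert e_mean[0] == pytest.approx(total_energy(toy3, hot))
        # monotone decay within noise: late mean far below early mean
        assert e_mean[-50:].mean() < 0.2 * e_mean[0]
        assert abs(e_mean[-50:].mean() - e_thermal) < 120.0

    def test_thermal_start_is_stationary(self):
        """A harmonic ensemble started from thermal samples shows no trend:
        the fitted slope of <E>(t) is consistent with zero."""
        from anhcascade.initial_conditions import sample_thermal_config

        system = make_harmonic_system([300.0, 500.0, 800.0])
        params = kmc.KmcParams(
            q=1.0, dt=5.0, t_max=2000.0, acceptance_mode="none",
            n_trajectories=60,
        )
        rng = rng_from_seed(17)
        starts = [sample_thermal_config(system, 300.0, rng) for _ in range(10)]
        times, e_mean = kmc.ensemble_energy(system, starts, params, rng)
        # early-half vs late-half drift, bounded by the analytic harmonic
        # ensemble spread (no independence credit for correlated times)
        kt = KB_CM1_PER_K * 300.0
        nbar = 1.0 / (np.exp(system.nu / kt) - 1.0)
        std_e = math.sqrt(float(np.sum(system.nu**2 * nbar * (nbar + 1.0))))
        n_traj = 60 * len(starts)
        sem = std_e / math.sqrt(n_traj)
        half = times.size // 2
        drift = e_mean[half:].mean() - e_mean[:half].mean()
        assert abs(drift) < 3.0 * math.sqrt(2.0) * sem


class TestEnsembleSpectra:
    def test_averaging_is_linear(self, toy3):
        params = kmc.KmcParams(
            q=0.5, dt=5.0, t_max=100.0, acceptance_mode="none",
            n_trajectories=3, spectral_window=(0.0, 2000.0), spectral_bin=10.0,
        )
        a = np.array([2, 0, 0])
        b = np.array([0, 1, 1])
        m_ab = kmc.ensemble_spectra(toy3, [a, b], params, rng_from_seed(5))
        m_a = kmc.ensemble_spectra(toy3, [a], params, rng_from_seed(5))
        # same seed: the first n_trajectories draws coincide
        np.testing.assert_allclose(
            m_ab.values * 2, m_a.values + (m_ab.values * 2 - m_a.values)
        )
        assert m_ab.samples[0] == 6

    def test_equilibrium_subtraction(self, toy3):
        params = kmc.KmcParams(
            q=0.5, dt=5.0, t_max=50.0, acceptance_mode="none",
            n_trajectories=2, spectral_window=(0.0, 2000.0), spectral_bin=10.0,
        )
        base = kmc.ensemble_spectra(toy3, [np.array([1, 0, 0])], params,
                                    rng_from_seed(3))
        eq_row = np.full(base.col_axis.size, 0.25)
        diff = kmc.ensemble_spectra(toy3, [np.array([1, 0, 0])], params,
                                    rng_from_seed(3), equilibrium_row=eq_row)
        np.testing.assert_allclose(diff.values, base.values - 0.25)
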