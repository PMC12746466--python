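"""Multicanonical sampler: proposal statistics, acceptance rule, flatness,
flat-histogram visitation and canonical reweighting against enumeration."""

import math

import numpy as np
import pytest
from scipy import stats

from anhcascade import muca_sampler as mu
from anhcascade import state_density as sd
from anhcascade.synthetic_fixtures import rng_from_seed
from anhcascade.vib_model import (
    VibrationalSystem,
    ground_transitions,
    stick_arrays,
    total_energy,
)


class TestProposal:
    def test_per_mode_move_rates(self, rng):
        """Empirical per-mode down/up frequencies match 1/N and r/N."""
        n = np.full(87, 3)
        r = 1.08
        downs = ups = 0
        trials = 3000
        for _ in range(trials):
            prop, _, _ = mu.propose_config(n, r, rng)
            moves = prop - n
            downs += int(np.sum(moves == -1))
            ups += int(np.sum(moves == 1))
        total = trials * 87
        assert downs / total == pytest.approx(1.0 / 87, rel=0.05)
        assert ups / total == pytest.approx(1.08 / 87, rel=0.05)

    def test_mean_quanta_drift_is_r_minus_one(self, rng):
        """For all n_i > 0 the expected change in total quanta per proposal
        is (r - 1)."""
        n = np.full(87, 2)
        deltas = [
            int(np.sum(mu.propose_config(n, 1.08, rng)[0]) - np.sum(n))
            for _ in range(4000)
        ]
        sem = np.std(deltas) / math.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(0.08, abs=4 * sem)

    def test_all_stay_at_origin_possible(self, rng):
        n = np.zeros(5, dtype=int)
        seen_identical = False
        for _ in range(50):
            prop, _, _ = mu.propose_config(n, 1.08, rng)
            assert np.all(prop >= 0)
            if np.array_equal(prop, n):
                seen_identical = True
        assert seen_identical

    def test_generation_ratio_equals_r_power_dn(self, rng):
        """log g_rev - log g_fwd = dn * log r, including at the n_i = 0
        boundary."""
        n = np.array([0, 1, 3, 0, 2])
        for _ in range(200):
            prop, lf, lr = mu.propose_config(n, 1.3, rng)
            dn = int(np.sum(n) - np.sum(prop))
            assert lr - lf == pytest.approx(dn * math.log(1.3), abs=1e-12)

    def test_r_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            mu.propose_config(np.zeros(2, dtype=int), 1.5, rng)


class TestValidateAndAcceptance:
    def test_ground_config_valid_in_base_window(self, one_mode_harmonic):
        w = mu.EnergyWindow(0.0, 1600.0, 16.0)
        assert mu.validate_config(one_mode_harmonic, np.array([0]), w)

    def test_negative_fundamental_invalidates(self):
        system = VibrationalSystem([100.0], [[-30.0]], [1.0])
        w = mu.EnergyWindow(0.0, 1600.0, 16.0)
        # n=1: dE(1->2) = 100 - 120 < 0
        assert not mu.validate_config(system, np.array([1]), w)

    def test_energy_outside_window_invalidates(self, one_mode_harmonic):
        w = mu.EnergyWindow(0.0, 800.0, 16.0)
        assert not mu.validate_config(one_mode_harmonic, np.array([1]), w)

    def test_acceptance_identity(self):
        dos = sd.DensityOfStates(16.0, np.array([10, 10], dtype=object))
        assert mu.muca_acceptance(dos, 8.0, 8.0, 1.08, 0) == 1.0

    def test_acceptance_hand_value(self):
        dos = sd.DensityOfStates(16.0, np.array([10, 20], dtype=object))
        p = mu.muca_acceptance(dos, 8.0, 24.0, 1.08, -1)
        assert p == pytest.approx(0.5 / 1.08, rel=1e-12)

    def test_acceptance_capped_at_one(self):
        dos = sd.DensityOfStates(16.0, np.array([20, 10], dtype=object))
        assert mu.muca_acceptance(dos, 8.0, 24.0, 1.08, 1) == 1.0

    def test_zero_density_proposal_rejected(self):
        dos = sd.DensityOfStates(16.0, np.array([10, 0], dtype=object))
        assert mu.muca_acceptance(dos, 8.0, 24.0, 1.08, 0) == 0.0


class TestFlatness:
    def test_uniform_histogram_flat(self):
        assert mu.flatness(np.full(8, 33), alpha=0.01)

    def test_hand_case_not_flat(self):
        assert not mu.flatness(np.array([100, 100, 160]), alpha=0.25)

    def test_single_bin_flat(self):
        assert mu.flatness(np.array([7]), alpha=0.25)

    def test_zero_mean_not_flat(self):
        assert not mu.flatness(np.zeros(3), alpha=0.25)

    def test_mask_excludes_unreachable_bins(self):
        h = np.array([50, 55, 0])
        assert mu.flatness(h, 0.25, mask=np.array([True, True, False]))
        assert not mu.flatness(h, 0.25)


def _walk_small_system(system, window, dos, seed, **kw):
    params = mu.MucaParams(
        max_steps=200_000, check_every=200,
        spectral_window=(0.0, 2000.0), spectral_bin=4.0, **kw,
    )
    return params, mu.run_walk(
        system, window, params, dos, rng_from_seed(seed), track_configs=True
    )


class TestRunWalk:
    def test_flat_histogram_three_levels(self, one_mode_harmonic):
        """A 1-mode harmonic walk visits its 3 window states uniformly."""
        window = mu.EnergyWindow(0.0, 2096.0, 16.0)
        dos = sd.count_states(one_mode_harmonic, 2096.0, 16.0)
        params, res = _walk_small_system(one_mode_harmonic, window, dos, 3)
        assert res.flat
        occupied = res.histogram[res.histogram > 0]
        assert occupied.size == 3
        mean = occupied.mean()
        assert np.all(np.abs(occupied - mean) / mean < params.alpha)
        # bookkeeping: samples vector equals histogram
        np.testing.assert_array_equal(res.matrix.samples, res.histogram)

    def test_within_bin_visitation_uniform(self):
        """Configurations sharing an energy bin are visited uniformly
        (chi-squared over pooled walks, fixed seed)."""
        from anhcascade.synthetic_fixtures import FixtureSpec, make_toy_anharmonic

        import warnings

        # diagonal X only: the separable density is exact, so the flat
        # histogram law holds strictly within every bin
        dense = make_toy_anharmonic(
            FixtureSpec(
                n_modes=3, freq_range=(120.0, 350.0),
                diag_range=(-6.0, -2.0), offdiag_scale=0.0, seed=9,
            )
        )
        e_max = 1200.0
        window = mu.EnergyWindow(0.0, e_max, 100.0)
        dos = sd.count_states(dense, e_max, 100.0)
        visits: dict[tuple, int] = {}
        # fixed-length walks (no flatness stop) with thinned tracking, so
        # the chi-squared samples are approximately independent
        params = mu.MucaParams(
            max_steps=250_000, check_every=1_000_000,
            spectral_window=(0.0, 2000.0), spectral_bin=4.0,
        )
        for walk_seed in (11, 12):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = mu.run_walk(
                    dense, window, params, dos, rng_from_seed(walk_seed),
                    track_configs=True, track_every=200,
                )
            for cfg, count in res.visits.items():
                visits[cfg] = visits.get(cfg, 0) + count
        by_bin: dict[int, list[int]] = {}
        for cfg, count in visits.items():
            b = window.bin_of(total_energy(dense, np.array(cfg)))
            by_bin.setdefault(b, []).append(count)
        chi_total = 0.0
        dof_total = 0
        tested = 0
        for b, counts in sorted(by_bin.items()):
            if len(counts) >= 3 and sum(counts) >= 5 * len(counts):
                chi, _ = stats.chisquare(counts)
                chi_total += chi
                dof_total += len(counts) - 1
                tested += 1
        assert tested >= 2
        p = stats.chi2.sf(chi_total, dof_total)
        assert p > 0.01, f"within-bin visitation not uniform (combined p={p:.4f})"

    def test_canonical_spectrum_matches_enumeration(self, toy3):
        """Boltzmann-reweighted MUCA spectrum at 300 K equals the exact
        canonical average over enumerated configurations within 2%
        integrated absolute deviation."""
        e_max = 1600.0
        bw = 16.0
        dos = sd.count_states(toy3, e_max, bw)
        windows = [mu.EnergyWindow(0.0, 800.0, bw), mu.EnergyWindow(800.0, e_max, bw)]
        params = mu.MucaParams(
            n_walks=3, max_steps=300_000, check_every=200,
            spectral_window=(0.0, 2000.0), spectral_bin=4.0,
        )
        rng = rng_from_seed(21)
        results = mu.run_windows(toy3, windows, params, dos, rng)
        spec = mu.assemble_canonical_spectrum(results, dos, 300.0)

        exact = _exact_canonical_row(toy3, e_max, windows, 300.0, params)
        dev = np.abs(spec.values - exact).sum() / exact.sum()
        assert dev < 0.02

    def test_doubled_samples_leave_assembly_invariant(self, toy3):
        dos = sd.count_states(toy3, 800.0, 16.0)
        window = mu.EnergyWindow(0.0, 800.0, 16.0)
        params, res = _walk_small_system(toy3, window, dos, 5, n_walks=1)
        spec1 = mu.assemble_canonical_spectrum([[res]], dos, 300.0)
        doubled = mu.WalkResult(
            res.window, res.histogram * 2,
            mu.SpectralMatrix(
                res.matrix.row_axis, res.matrix.col_axis,
                res.matrix.values * 2, res.matrix.samples * 2,
            ),
            res.flat, res.steps,
        )
        spec2 = mu.assemble_canonical_spectrum([[doubled]], dos, 300.0)
        np.testing.assert_allclose(spec2.values, spec1.values, rtol=1e-12)


def _exact_canonical_row(system, e_max, windows, temperature, params):
    """Independent oracle: Boltzmann average of per-bin mean stick rows over
    the brute-force enumerated configurations, using the same validity rule,
    binning and weighting as the sampler."""
    bw = windows[0].bin_width
    dos = sd.count_states(system, e_max, bw)
    w_bins = sd.boltzmann_weights(dos, temperature)
    lo, hi = params.spectral_window
    ncol = int(round((hi - lo) / params.spectral_bin))
    rows = {}
    counts = {}
    ref = ground_transitions(system)
    full_window = mu.EnergyWindow(windows[0].e_lo, windows[-1].e_hi, bw)
    for cfg, e in sd.brute_force_states(system, e_max):
        if not mu.validate_config(system, cfg, full_window):
            continue
        b = int(math.floor(e / bw + 1e-9))
        pos, inten, _, _, _ = stick_arrays(system, cfg, ref)
        row = np.zeros(ncol)
        sel = (inten > 0) & (pos >= lo) & (pos < hi)
        idx = ((pos[sel] - lo) / params.spectral_bin).astype(int)
        np.add.at(row, idx, inten[sel])
        rows[b] = rows.get(b, np.zeros(ncol)) + row
        counts[b] = counts.get(b, 0) + 1
    out = np.zeros(ncol)
    norm = sum(w_bins[b] for b in rows)
    for b, row in rows.items():
        out += (w_bins[b] / norm) * row / counts[b]
    return out


class TestFindInitial:
    def test_finds_valid_config_in_high_window(self, toy3, rng):
        window = mu.EnergyWindow(800.0, 1600.0, 16.0)
        n = mu.find_initial_config(toy3, window, rng)
        assert mu.validate_config(toy3, n, window)

    def test_unreachable_window_raises(self, one_mode_harmonic, rng):
        window = mu.EnergyWindow(16.0, 32.0, 16.0)  # between levels
        with pytest.raises(RuntimeError):
            mu.find_initial_config(one_mode_harmonic, window, rng, max_tries=50)
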