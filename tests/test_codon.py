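"""NG86 counting, GY94 likelihood machinery, LRT and Ks dating."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

import bgcpipe as b
from bgcpipe.codon import (
    SENSE_CODONS,
    CodonPair,
    build_rate_matrix,
    clean_alignment,
    divergence_time,
    equal_frequencies,
    f3x4_frequencies,
    gy94_fit,
    lrt,
    ng86,
    pair_log_likelihood,
    transition_matrix,
    _pair_counts,
)


class TestCleanAlignment:
    def test_gap_column_dropped(self):
        pair = clean_alignment("ATG---AAA", "ATGCCCAAA")
        assert pair.seq_a == "ATGAAA" and pair.seq_b == "ATGAAA"

    def test_stop_codon_column_dropped(self):
        pair = clean_alignment("TAAATG", "TACATG")
        assert pair.n_codons == 1
        assert pair.seq_a == "ATG"

    def test_clean_input_is_identity(self):
        pair = clean_alignment("ATGAAA", "ATGCCC")
        assert (pair.seq_a, pair.seq_b) == ("ATGAAA", "ATGCCC")

    def test_everything_dirty_is_an_error(self):
        with pytest.raises(ValueError, match="no clean codon"):
            clean_alignment("NNN", "AAA")

    def test_codon_pair_rejects_internal_stops(self):
        with pytest.raises(ValueError, match="stop"):
            CodonPair("ATGTAAAAA", "ATGAAAAAA")


class TestNG86:
    def test_identical_sequences(self):
        r = ng86(CodonPair("ATGAAA", "ATGAAA"))
        assert r.Sd == r.Nd == 0
        assert r.dS == r.dN == 0
        assert r.omega is None

    def test_hand_enumerated_single_codon(self):
        # TTT vs GTT: S=(1/3+1)/2=2/3, N=7/3, one nonsyn difference
        r = ng86(CodonPair("TTT", "GTT"))
        assert r.S_sites == pytest.approx(2 / 3)
        assert r.N_sites == pytest.approx(7 / 3)
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.pN == pytest.approx(3 / 7)
        assert r.dN == pytest.approx(-0.75 * math.log(3 / 7), abs=1e-12)
        assert r.dS == 0.0

    def test_site_counts_sum_to_sequence_length(self):
        pair = b.simulate_codon_pair(0.2, 2.0, 0.5, 100, seed=4)
        r = ng86(pair)
        assert r.S_sites + r.N_sites == pytest.approx(3 * pair.n_codons)

    def test_symmetric_in_sequence_order(self):
        pair = b.simulate_codon_pair(0.4, 1.5, 0.7, 80, seed=6)
        a = ng86(pair)
        c = ng86(CodonPair(pair.seq_b, pair.seq_a))
        assert a == c

    def test_saturation_flagged_as_infinite(self):
        # maximally different codons drive pN far beyond the JC limit
        r = ng86(CodonPair("TTTTTT", "AGGAGG"))
        assert r.saturated
        assert math.isinf(r.dN)

    def test_recovers_simulated_omega_scale(self):
        omegas = []
        for seed in range(15):
            pair = b.simulate_codon_pair(0.2, 2.0, 0.5, 500, seed=100 + seed)
            r = ng86(pair)
            omegas.append(r.omega)
        assert 0.3 < np.median(omegas) < 0.8


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.2), (1.0, 1.0), (5.0, 3.0)])
    def test_rows_sum_to_zero_and_detailed_balance(self, kappa, omega):
        pi = equal_frequencies()
        q = build_rate_matrix(kappa, omega, pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14
        assert -np.sum(pi * np.diag(q)) == pytest.approx(1.0)

    def test_pi_is_stationary_for_all_t(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        q = build_rate_matrix(2.0, 0.3, pi)
        for t in (0.1, 1.0, 5.0):
            p = transition_matrix(q, pi, t)
            assert pi @ p == pytest.approx(pi, abs=1e-10)
            assert p.sum(axis=1) == pytest.approx(np.ones(61), abs=1e-10)

    def test_transition_matrix_matches_scipy_expm(self):
        pi = equal_frequencies()
        q = build_rate_matrix(3.0, 0.7, pi)
        for t in (0.05, 0.5, 2.0):
            assert transition_matrix(q, pi, t) == pytest.approx(expm(q * t), abs=1e-10)


class TestGY94Fit:
    def test_loglik_matches_expm_oracle_on_random_points(self, small_codon_pair):
        counts = _pair_counts(small_codon_pair)
        pi = f3x4_frequencies(small_codon_pair)
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.uniform(0.02, 3.0)
            kappa = rng.uniform(0.2, 8.0)
            omega = rng.uniform(0.05, 4.0)
            q = build_rate_matrix(kappa, omega, pi)
            p = expm(q * t)
            oracle = float(np.sum(counts * np.log(pi[:, None] * p + 1e-300)))
            assert pair_log_likelihood(counts, t, kappa, omega, pi) == pytest.approx(
                oracle, abs=1e-6
            )

    def test_identical_pair_drives_t_to_lower_bound(self):
        pair = CodonPair("ATGAAACCCGGG" * 10, "ATGAAACCCGGG" * 10)
        fit = gy94_fit(pair, freqs="equal")
        assert fit.t_hat < 1e-4
        # at t ~ 0 the likelihood approaches sum(log pi) over sites
        assert fit.logL == pytest.approx(40 * math.log(1 / 61), rel=1e-3)

    def test_parameter_recovery_on_simulated_pair(self, small_codon_pair):
        fit = gy94_fit(small_codon_pair)
        assert fit.converged
        assert 0.1 < fit.omega_hat < 0.5
        assert 0.15 < fit.t_hat < 0.6
        assert 1.0 < fit.kappa_hat < 4.0

    def test_symmetric_in_sequence_order(self, small_codon_pair):
        fit_ab = gy94_fit(small_codon_pair)
        fit_ba = gy94_fit(CodonPair(small_codon_pair.seq_b, small_codon_pair.seq_a))
        assert fit_ba.logL == pytest.approx(fit_ab.logL, abs=1e-6)
        assert fit_ba.omega_hat == pytest.approx(fit_ab.omega_hat, rel=1e-3)

    def test_fixed_omega_never_beats_free(self, small_codon_pair):
        free = gy94_fit(small_codon_pair)
        fixed = gy94_fit(small_codon_pair, fix_omega=1.0)
        assert fixed.omega_fixed and fixed.omega_hat == 1.0
        assert free.logL >= fixed.logL - 1e-6


class TestLRT:
    def _fit(self, logL, fixed=False):
        return b.MLFit(
            t_hat=0.3, kappa_hat=2.0, omega_hat=1.0 if fixed else 0.4,
            logL=logL, converged=True, omega_fixed=fixed,
        )

    def test_equal_likelihoods_give_p_one(self):
        res = lrt(self._fit(-100.0), self._fit(-100.0, fixed=True))
        assert res.stat == 0.0 and res.p == 1.0 and not res.significant

    def test_critical_value_of_chi2_df1(self):
        res = lrt(self._fit(-100.0), self._fit(-100.0 - 3.841459 / 2, fixed=True))
        assert res.p == pytest.approx(0.05, abs=1e-6)

    def test_stat_invariant_to_constant_shift(self):
        a = lrt(self._fit(-100.0), self._fit(-102.0, fixed=True))
        c = lrt(self._fit(-1100.0), self._fit(-1102.0, fixed=True))
        assert a.stat == pytest.approx(c.stat)

    def test_free_below_fixed_is_an_optimizer_error(self):
        with pytest.raises(ValueError, match="dominate"):
            lrt(self._fit(-105.0), self._fit(-100.0, fixed=True))

    def test_fixed_fit_must_have_omega_one(self):
        bad = b.MLFit(0.3, 2.0, 0.5, -100.0, True, omega_fixed=True)
        with pytest.raises(ValueError, match="omega fixed at 1"):
            lrt(self._fit(-99.0), bad)


class TestDivergenceTime:
    def test_zero_ks_is_zero_years(self):
        assert divergence_time(0.0).time_years == 0.0

    @pytest.mark.parametrize(
        "ks,expected_my", [(0.3705, 28.5), (0.13, 10.0), (0.8463, 65.1)]
    )
    def test_clock_arithmetic(self, ks, expected_my):
        est = divergence_time(ks)
        assert est.time_years / 1e6 == pytest.approx(expected_my, rel=1e-3)

    def test_linear_in_ks_inverse_in_rate(self):
        a = divergence_time(0.2, rate=1e-8)
        c = divergence_time(0.4, rate=2e-8)
        assert a.time_years == pytest.approx(c.time_years)
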