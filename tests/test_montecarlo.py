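"""Tests for the Monte Carlo design-evaluation engine and sweeps.

The gaussian-log noise channel is the closed-form oracle: under additive
i.i.d. Gaussian noise on ln m the least-squares covariance formula
sigma^2 * M^{-1} is exact, so the engine's empirical moments must match it.
"""

import math

import numpy as np
import pytest

from adcdesign import (
    AcquisitionDesign,
    DegenerateDesignError,
    MonoexpParams,
    NoiseSpec,
    compare_designs,
    d_optimal_design,
    evaluate_design,
    lse_covariance,
    resolve_design,
    sweep,
)

PARAMS = MonoexpParams(m0=500.0, D=1e-3)


class TestEvaluateDesign:
    def test_gaussian_log_channel_matches_closed_form(self):
        sigma = 0.1
        design = AcquisitionDesign((0.0, 2000.0))
        res = evaluate_design(
            design, PARAMS, NoiseSpec("gaussian-log", sigma), n_mc=20_000, seed=11
        )
        expected_std = math.sqrt(lse_covariance(design, sigma)[1, 1])
        assert res.std_D == pytest.approx(expected_std, rel=0.05)
        assert abs(res.bias_D) < 3 * res.mc_se_D
        # x_hat is unbiased; m0_hat = exp(x_hat[0]) carries the exact
        # lognormal offset m0 * (exp(Var(ln m0_hat)/2) - 1)
        jensen = PARAMS.m0 * math.expm1(lse_covariance(design, sigma)[0, 0] / 2)
        assert abs(res.bias_m0 - jensen) < 3 * res.mc_se_m0

    def test_gaussian_log_covariance_frobenius(self):
        # full covariance of (ln m0_hat, D_hat), not just Var(D_hat)
        sigma = 0.1
        design = d_optimal_design(6, 0.0, 2000.0)
        noise = NoiseSpec("gaussian-log", sigma)
        n_mc = 20_000
        # re-simulate to get the joint draws via the same substream
        from adcdesign._rand import rng
        from adcdesign.estimation import batch_loglinear_lse
        from adcdesign.model import design_matrix, signal

        clean = signal(PARAMS, design.as_array())
        meas = noise.apply(np.broadcast_to(clean, (n_mc, design.n)), rng(11))
        X = batch_loglinear_lse(design_matrix(design), np.log(meas))
        emp = np.cov(X.T)
        expected = lse_covariance(design, sigma)
        frob = np.linalg.norm(emp - expected) / np.linalg.norm(expected)
        assert frob < 0.05
        # the log-linear parameter vector itself is unbiased
        se = np.sqrt(np.diag(expected) / n_mc)
        np.testing.assert_array_less(np.abs(X.mean(axis=0) - PARAMS.x), 3 * se)

    def test_zero_noise_is_exact(self):
        res = evaluate_design(
            AcquisitionDesign((0.0, 1000.0, 2000.0)),
            PARAMS,
            NoiseSpec(sigma_G=0.0),
            n_mc=100,
            seed=0,
        )
        assert res.bias_D == pytest.approx(0.0, abs=1e-15)
        assert res.std_D == pytest.approx(0.0, abs=1e-15)
        assert res.n_failed == 0

    def test_rician_high_snr_small_bias(self):
        # SNR = 100 and b_max * D <= 0.5: Gaussian-approximation regime
        p = MonoexpParams(m0=500.0, D=0.25e-3)
        res = evaluate_design(
            d_optimal_design(10, 0.0, 2000.0),
            p,
            NoiseSpec(sigma_G=5.0),
            n_mc=20_000,
            seed=13,
        )
        assert abs(res.bias_D) / p.D < 0.01

    def test_precision_independent_of_d_under_gaussian_log(self):
        # det M does not involve D, so std_D cannot either (up to MC error)
        design = d_optimal_design(10, 0.0, 2000.0)
        noise = NoiseSpec("gaussian-log", 0.1)
        stds = [
            evaluate_design(
                design, MonoexpParams(500.0, D), noise, n_mc=20_000, seed=17
            ).std_D
            for D in (0.3e-3, 1e-3, 3e-3)
        ]
        assert max(stds) / min(stds) < 1.05

    def test_mc_se_definition(self):
        res = evaluate_design(
            AcquisitionDesign((0.0, 2000.0)),
            PARAMS,
            NoiseSpec(sigma_G=25.0),
            n_mc=5000,
            seed=3,
        )
        assert res.mc_se_D == pytest.approx(res.std_D / math.sqrt(res.n_mc))

    def test_degenerate_design_rejected_before_simulation(self):
        with pytest.raises(DegenerateDesignError):
            evaluate_design(
                AcquisitionDesign((700.0, 700.0)), PARAMS, NoiseSpec(sigma_G=1.0), 100, 0
            )

    def test_reproducible_given_seed(self):
        args = (AcquisitionDesign((0.0, 2000.0)), PARAMS, NoiseSpec(sigma_G=50.0), 2000)
        assert evaluate_design(*args, seed=5) == evaluate_design(*args, seed=5)


class TestCompareDesigns:
    def test_common_random_numbers_make_duplicates_identical(self):
        results = compare_designs(
            ["dopt", "dopt"], PARAMS, NoiseSpec(sigma_G=50.0), 2000, seed=1
        )
        assert results[0][1] == results[1][1]

    def test_dopt_beats_gcrlb_two_point_at_low_d(self):
        # two-point comparison at D = 0.3e-3, SNR 10
        p = MonoexpParams(500.0, 0.3e-3)
        results = dict(
            compare_designs(
                ["dopt", "gcrlb"], p, NoiseSpec(sigma_G=50.0), 20_000, seed=2, N=2
            )
        )
        assert results["dopt"].std_D < results["gcrlb"].std_D

    def test_gcrlb_underestimates_m0_at_high_d(self):
        # at D = 3e-3 the ten-point GCRLB design severely underestimates m0
        p = MonoexpParams(500.0, 3e-3)
        results = dict(
            compare_designs(
                ["dopt", "gcrlb"], p, NoiseSpec(sigma_G=50.0), 20_000, seed=2, N=10
            )
        )
        assert results["gcrlb"].bias_m0 < 0
        assert abs(results["gcrlb"].bias_m0) > abs(results["dopt"].bias_m0)


class TestSweep:
    def test_degenerate_single_cell_equals_direct_evaluation(self):
        table = sweep("D", [1e-3], ["dopt"], n_mc=2000, seed=9)
        assert len(table.frame) == 1
        row = table.frame.iloc[0]
        from adcdesign._rand import child_seed

        direct = evaluate_design(
            resolve_design("dopt", 10, 0.0, 2000.0),
            PARAMS,
            NoiseSpec(sigma_G=50.0),
            2000,
            child_seed(9, 0),
        )
        assert row.bias_D == direct.bias_D
        assert row.std_D == direct.std_D

    def test_methods_identical_at_n2(self):
        table = sweep("N", [2, 4], ["dopt", "ed"], n_mc=2000, seed=5)
        at2 = table.frame[table.frame.value == 2]
        assert at2.iloc[0].std_D == at2.iloc[1].std_D
        assert at2.iloc[0].bias_D == at2.iloc[1].bias_D

    def test_std_decreases_with_n(self):
        table = sweep("N", [2, 6, 12, 20], ["dopt", "ed"], n_mc=20_000, seed=5)
        for method in ("dopt", "ed"):
            stds = table.frame[table.frame.method == method].sort_values("value").std_D
            assert stds.is_monotonic_decreasing

    def test_rows_carry_full_context(self):
        table = sweep("b_max", [1000.0], ["dopt"], n_mc=100, seed=0)
        row = table.frame.iloc[0]
        for col in ("m0", "D", "N", "b_min", "b_max", "snr", "seed", "n_mc"):
            assert col in row.index

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            sweep("sigma", [1.0], ["dopt"], n_mc=100, seed=0)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            sweep("D", [], ["dopt"], n_mc=100, seed=0)
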