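import numpy as np
import pytest

from movebreak import breakpoints as bp
from conftest import piecewise_signal


def hinge(n=120, psi=60.0, slope=-1.0, noise=0.0, seed=0, span=120.0):
    x = np.linspace(0, span, n)
    y = piecewise_signal(x, [psi], [0.0, slope])
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, n)
    return x, y


class TestFitPiecewise:
    def test_k0_recovers_exact_line(self):
        x = np.linspace(0, 100, 50)
        y = 2.5 - 0.75 * x
        fit = bp.fit_piecewise(x, y, 0)
        assert fit.slopes[0] == pytest.approx(-0.75, abs=1e-12)
        assert fit.intercept == pytest.approx(2.5, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_noise_free_hinge_breakpoint_located(self):
        x, y = hinge(n=240, psi=96.0, span=240.0)
        fit = bp.fit_piecewise_multistart(x, y, 1)
        assert fit.converged
        assert fit.psi[0] == pytest.approx(96.0, abs=0.5)
        assert fit.slopes[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.slopes[1] == pytest.approx(-1.0, abs=1e-6)

    def test_fitted_function_continuous_at_breakpoints(self):
        x, y = hinge(n=100, psi=40.0, noise=0.3, seed=1)
        fit = bp.fit_piecewise_multistart(x, y, 1)
        eps = 1e-7
        below = fit.predict(fit.psi[0] - eps)
        above = fit.predict(fit.psi[0] + eps)
        assert abs(above - below) < 1e-6 * (1 + abs(below))

    def test_shift_and_scale_invariance(self):
        x, y = hinge(n=80, psi=50.0, noise=0.4, seed=2)
        fit = bp.fit_piecewise_multistart(x, y, 1)
        shifted = bp.fit_piecewise_multistart(x, y + 10.0, 1)
        assert shifted.psi[0] == pytest.approx(fit.psi[0], abs=1e-6)
        assert shifted.intercept == pytest.approx(fit.intercept + 10.0, rel=1e-6)
        np.testing.assert_allclose(shifted.slopes, fit.slopes, atol=1e-8)
        scaled = bp.fit_piecewise_multistart(x, 3.0 * y, 1)
        assert scaled.psi[0] == pytest.approx(fit.psi[0], abs=1e-6)
        np.testing.assert_allclose(scaled.slopes, 3.0 * fit.slopes, rtol=1e-6)
        assert scaled.rss == pytest.approx(9.0 * fit.rss, rel=1e-6)

    def test_insufficient_data_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(bp.FitError):
            bp.fit_piecewise(x, x, 1)  # needs 3*(k+1)+k = 7
        with pytest.raises(bp.FitError):
            bp.fit_piecewise(np.ones(20), np.ones(20), 1)  # all-equal x
        with pytest.raises(bp.FitError):
            bp.fit_piecewise(np.arange(20.0), np.ones(20), -1)


class TestAicc:
    def test_penalty_monotone_in_k_at_equal_rss(self):
        # equal fit quality: the simpler model always scores lower
        scores = [bp.aicc(100.0, 60, k) for k in range(4)]
        assert scores == sorted(scores)

    def test_converges_to_aic_for_large_n(self):
        p = 5  # k = 1
        aic = 10_000 * np.log(123.0 / 10_000) + 2 * p
        assert bp.aicc(123.0, 10_000, 1) == pytest.approx(aic, abs=0.02)

    def test_hinge_prefers_one_breakpoint(self):
        x, y = hinge(n=100, psi=40.0, noise=0.2, seed=3)
        f0 = bp.fit_piecewise(x, y, 0)
        f1 = bp.fit_piecewise_multistart(x, y, 1)
        assert f1.aicc < f0.aicc

    def test_small_sample_guard(self):
        with pytest.raises(bp.FitError):
            bp.aicc(10.0, 6, 1)  # n <= p + 1


class TestRankModels:
    def test_rss_non_increasing_in_k(self):
        rng = np.random.default_rng(4)
        x = np.arange(120, dtype=float)
        y = piecewise_signal(x, [40.0, 80.0], [0.5, -0.5, 0.2]) + rng.normal(0, 0.4, 120)
        ranking = bp.rank_models(x, y, kmax=4)
        ks = sorted(ranking.fits)
        rss = [ranking.fits[k].rss for k in ks]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_selected_within_parsimony_band_of_minimum_aicc(self):
        x, y = hinge(n=100, psi=40.0, noise=0.3, seed=5)
        ranking = bp.rank_models(x, y, kmax=3)
        best_aicc = min(f.aicc for f in ranking.fits.values())
        assert ranking.selected.aicc <= best_aicc + 2.0 + 1e-9
        # no simpler model is equally supported
        for k, f in ranking.fits.items():
            if k < ranking.selected_k:
                assert f.aicc > best_aicc + 2.0

    def test_two_breakpoint_signal_recovered(self):
        x = np.arange(150, dtype=float)
        y = piecewise_signal(x, [50.0, 100.0], [0.0, 1.0, -0.2])
        ranking = bp.rank_models(x, y, kmax=4)
        assert ranking.selected_k == 2
        np.testing.assert_allclose(ranking.selected.psi, [50.0, 100.0], atol=1.0)


class TestValidateBreakpoints:
    def test_flag_consistency_on_flat_noise(self):
        # pure-noise fits may legitimately fail to converge; take the first
        # few that do and check the accept flag is tied to slope significance
        x = np.arange(100, dtype=float)
        checked = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            try:
                fit = bp.fit_piecewise_multistart(x, rng.normal(0, 1, 100), 1)
            except bp.FitError:
                continue
            val = bp.validate_breakpoints(fit)
            assert val.accepted[0] == (val.slope_significant[0] or val.slope_significant[1])
            checked += 1
        assert checked >= 3

    def test_steep_hinge_accepted(self):
        x, y = hinge(n=120, psi=60.0, slope=-1.0, noise=0.1, seed=7)
        fit = bp.fit_piecewise_multistart(x, y, 1)
        val = bp.validate_breakpoints(fit)
        assert val.accepted[0]

    def test_acceptance_monotone_in_snr(self):
        accepted_at = []
        for slope in (0.001, 0.01, 0.1, 1.0):
            hits = 0
            for seed in range(10):
                x, y = hinge(n=100, psi=50.0, slope=slope, noise=1.0, seed=seed)
                try:
                    fit = bp.fit_piecewise(x, y, 1, init=np.array([50.0]))
                except bp.FitError:
                    continue
                if fit.converged and bp.validate_breakpoints(fit).accepted[0]:
                    hits += 1
            accepted_at.append(hits)
        assert accepted_at[-1] >= accepted_at[0]
        assert accepted_at[-1] >= 9  # strong slopes essentially always accepted


class TestBootstrap:
    def test_deterministic_given_seed(self):
        x, y = hinge(n=100, psi=50.0, noise=0.5, seed=8)
        a = bp.bootstrap_breakpoints(x, y, 1, B=30, seed=11)
        b = bp.bootstrap_breakpoints(x, y, 1, B=30, seed=11)
        assert [(e.ci_low, e.ci_high) for e in a] == [(e.ci_low, e.ci_high) for e in b]

    def test_noise_free_hinge_ci_tight(self):
        x, y = hinge(n=240, psi=96.0, span=240.0)
        ests = bp.bootstrap_breakpoints(x, y, 1, B=50, seed=0)
        assert ests[0].ci_high - ests[0].ci_low < 2.0
        assert ests[0].ci_low - 1e-9 <= ests[0].psi <= ests[0].ci_high + 1e-9

    def test_residual_bootstrap_available(self):
        x, y = hinge(n=100, psi=50.0, noise=0.5, seed=9)
        ests = bp.bootstrap_breakpoints(x, y, 1, B=20, seed=1, method="residual")
        assert ests[0].n_boot_converged > 0


class TestGridSearch:
    def test_grid_matches_known_optimum(self):
        # noise-free hinge at an observed x: grid must find it exactly
        x = np.arange(40, dtype=float)
        y = piecewise_signal(x, [25.0], [0.0, 2.0])
        psi, rss = bp.grid_search_fit(x, y, 1)
        assert psi[0] == pytest.approx(25.0)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_iterative_fit_matches_grid_on_small_problems(self):
        rng = np.random.default_rng(10)
        for k in (1, 2):
            x = np.arange(50, dtype=float)
            psi = [18.0] if k == 1 else [15.0, 33.0]
            slopes = [0.3] + [0.3 + s for s in ([1.2] if k == 1 else [1.2, -0.9])]
            # slopes as cumulative values
            sl = [0.3]
            for d in ([1.2] if k == 1 else [1.2, -2.1]):
                sl.append(sl[-1] + d)
            y = piecewise_signal(x, psi, sl) + rng.normal(0, 0.5, 50)
            fit = bp.fit_piecewise_multistart(x, y, k)
            _, grss = bp.grid_search_fit(x, y, k)
            assert fit.rss <= 1.01 * grss
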