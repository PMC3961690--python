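"""Tests for per-resonance pKa fitting, model selection and aggregation."""

import numpy as np
import pytest

from trxpka.fitting import (
    FitError,
    NoTitrationError,
    TitrationSeries,
    aggregate_pka,
    fit_one_pka,
    fit_two_pka,
    microscopic_pair_from_fit,
    select_model,
)
from trxpka.models import OnePkaParams, TwoPkaParams, shift_one_pka, shift_two_pka
from trxpka.simulate import TitrationSimSpec, default_ph_grid, gen_titration

GRID = default_ph_grid(0.5)
GRID_FINE = default_ph_grid(0.25)


def make_series(params, grid=GRID, noise_sd=0.0, seed=0):
    if isinstance(params, OnePkaParams):
        clean = shift_one_pka(grid, params)
    else:
        clean = shift_two_pka(grid, params)
    noise = np.random.default_rng(seed).normal(0, noise_sd, grid.shape) if noise_sd else 0.0
    return TitrationSeries("test", "res", grid, clean + noise)


class TestFitOnePka:
    def test_noiseless_exact_recovery(self):
        fit = fit_one_pka(make_series(OnePkaParams(28.0, 30.5, 10.6)))
        assert fit.params.pka == pytest.approx(10.6, abs=1e-6)
        assert fit.converged and not fit.extrapolated

    def test_noisy_recovery_within_tolerance(self):
        fit = fit_one_pka(make_series(OnePkaParams(28.0, 30.5, 10.6), noise_sd=0.05, seed=3))
        assert fit.params.pka == pytest.approx(10.6, abs=0.1)
        assert fit.stderr_pka[0] is not None and fit.stderr_pka[0] > 0

    def test_flat_series_raises_no_titration(self):
        rng = np.random.default_rng(0)
        flat = TitrationSeries("t", "r", GRID, 28.0 + rng.normal(0, 0.05, GRID.shape))
        with pytest.raises(NoTitrationError):
            fit_one_pka(flat)

    def test_constant_series_raises_no_titration(self):
        with pytest.raises(NoTitrationError):
            fit_one_pka(TitrationSeries("t", "r", GRID, np.full(GRID.shape, 28.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_one_pka(make_series(OnePkaParams(28.0, 30.5, 8.0), grid=np.linspace(4, 13, 5)))

    def test_pka_outside_window_flagged_extrapolated(self):
        grid = np.linspace(4.0, 9.0, 15)
        fit = fit_one_pka(make_series(OnePkaParams(28.0, 30.5, 11.5), grid=grid))
        assert fit.extrapolated

    def test_noise_free_identifiability_random_draws(self):
        """Noiseless one-pKa fits recover truth to 1e-5 over random parameters."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            truth = OnePkaParams(
                rng.uniform(10, 60),
                rng.uniform(10, 60) + rng.uniform(0.3, 3.0),
                rng.uniform(5, 12),
            )
            fit = fit_one_pka(make_series(truth))
            assert fit.params.pka == pytest.approx(truth.pka, abs=1e-5)

    def test_monte_carlo_bias_and_spread(self):
        """At 0.05 ppm noise on a 19-point grid the estimator is nearly
        unbiased with small spread across repeated simulations."""
        truth = OnePkaParams(28.0, 30.5, 9.0)
        estimates = []
        for seed in range(200):
            fit = fit_one_pka(make_series(truth, noise_sd=0.05, seed=seed))
            estimates.append(fit.params.pka)
        estimates = np.array(estimates)
        assert abs(estimates.mean() - truth.pka) < 0.02
        assert estimates.std(ddof=1) < 0.05


class TestFitTwoPka:
    TRUTH = TwoPkaParams(0.0, 1.35, 2.7, 7.6, 10.4)

    def test_noiseless_exact_recovery(self):
        fit = fit_two_pka(make_series(self.TRUTH, grid=GRID_FINE))
        assert fit.params.pka1 == pytest.approx(7.6, abs=1e-5)
        assert fit.params.pka2 == pytest.approx(10.4, abs=1e-5)

    def test_noisy_two_step_recovery(self):
        fit = fit_two_pka(make_series(self.TRUTH, grid=GRID_FINE, noise_sd=0.05, seed=2))
        assert fit.params.pka1 == pytest.approx(7.6, abs=0.15)
        assert fit.params.pka2 == pytest.approx(10.4, abs=0.15)
        assert not fit.non_identifiable

    def test_ordering_always_holds(self):
        for seed in range(10):
            fit = fit_two_pka(make_series(self.TRUTH, grid=GRID_FINE, noise_sd=0.1, seed=seed))
            assert fit.params.pka1 <= fit.params.pka2

    def test_single_transition_data_flagged_non_identifiable(self):
        series = make_series(OnePkaParams(28.0, 30.5, 10.6), grid=GRID_FINE, noise_sd=0.05, seed=1)
        fit = fit_two_pka(series)
        assert fit.non_identifiable

    def test_min_points_enforced(self):
        grid = np.linspace(4, 13, 7)
        with pytest.raises(FitError):
            fit_two_pka(make_series(self.TRUTH, grid=grid))

    def test_microscopic_pair_from_symmetric_fit(self):
        """A symmetric two-step fit inverts to microscopic values one
        statistical factor inside the macroscopic pair."""
        fit = fit_two_pka(make_series(TwoPkaParams(0.0, 1.35, 2.7, 7.299, 10.701), grid=GRID_FINE))
        low, high = microscopic_pair_from_fit(fit)
        assert low == pytest.approx(7.6, abs=1e-3)
        assert high == pytest.approx(10.4, abs=1e-3)


class TestSelectModel:
    def test_two_step_data_selects_two_pka(self):
        series = make_series(
            TwoPkaParams(0.0, 1.35, 2.7, 7.6, 10.4), grid=GRID_FINE, noise_sd=0.05, seed=4
        )
        assert select_model(series, alpha=0.05).chosen == "two_pka"

    def test_one_step_data_selects_one_pka(self):
        series = make_series(OnePkaParams(28.0, 30.5, 9.0), noise_sd=0.05, seed=5)
        assert select_model(series, alpha=0.05).chosen == "one_pka"

    def test_alpha_limits(self):
        series = make_series(OnePkaParams(28.0, 30.5, 9.0), noise_sd=0.05, seed=6)
        assert select_model(series, alpha=1.0).chosen == "two_pka"
        assert select_model(series, alpha=1e-300).chosen == "one_pka"


class TestAggregatePka:
    def _fits(self, values):
        out = []
        for v in values:
            s = make_series(OnePkaParams(28.0, 30.5, v))
            out.append(fit_one_pka(s))
        return out

    def test_mean_and_sample_sd(self):
        values = [10.5, 10.6, 10.7, 10.4, 10.6, 10.8, 10.6]
        est = aggregate_pka(self._fits(values))
        assert est.mean_pka == pytest.approx(np.mean(values), abs=1e-6)
        assert est.sd_pka == pytest.approx(np.std(values, ddof=1), abs=1e-6)
        assert est.sd_pka == pytest.approx(0.13, abs=0.005)
        assert est.n_resonances == 7

    def test_single_fit_sd_undefined(self):
        est = aggregate_pka(self._fits([10.6]))
        assert est.mean_pka == pytest.approx(10.6, abs=1e-5)
        assert est.sd_pka is None
        assert est.n_resonances == 1

    def test_permutation_invariance(self):
        fits = self._fits([10.5, 10.7, 10.6, 10.4])
        a = aggregate_pka(fits)
        b = aggregate_pka(fits[::-1])
        assert a == b

    def test_mixed_kinds_require_explicit_transition(self):
        one = self._fits([10.6])
        two = [fit_two_pka(make_series(TwoPkaParams(0, 1.35, 2.7, 7.6, 10.4), grid=GRID_FINE))]
        with pytest.raises(ValueError):
            aggregate_pka(one + two, transition="only")
        est = aggregate_pka(one + two, transition="upper")
        assert est.n_resonances == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pka([])

    def test_wild_type_style_aggregate_format(self):
        """Seven synthetic reduced-Cys resonances aggregate to the
        '10.6 ± 0.2 (7)' reporting convention."""
        from trxpka.io import format_pka_estimate

        spec = TitrationSimSpec(
            truth=OnePkaParams(28.0, 30.5, 10.6),
            noise_sd=0.05,
            n_resonances=7,
            amplitude_range=(0.5, 2.5),
            seed=20,
        )
        series, _ = gen_titration(spec)
        est = aggregate_pka([fit_one_pka(s) for s in series])
        text = format_pka_estimate(est)
        assert text.endswith("(7)")
        assert est.mean_pka == pytest.approx(10.6, abs=0.15)
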