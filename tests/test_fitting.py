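"""Curve fitting: round trips, initialization heuristics, mixture
behaviour, and the 3D model-robustness refit."""

import numpy as np
import pytest

from fcs3c.errors import ConfigurationError, DomainError, FitError
from fcs3c.fitting import fit_curve, init_heuristic, refit_3d_fixed_a
from fcs3c.models import (
    ConfocalGeometry,
    CorrelationCurve,
    SpeciesParams,
    default_lag_grid,
    eval_single_2d,
    eval_single_3d,
    eval_two_species,
)
from fcs3c.synthetic import CurveNoiseSpec, gen_curve


def mixture_curve(frac_slow, tau_fast=4.0, tau_slow=15.0, n_tot=1.0, grid=None):
    lags = default_lag_grid(1e-2, 1e3, 200) if grid is None else grid
    return eval_two_species(
        lags,
        SpeciesParams((1 - frac_slow) * n_tot, tau_fast),
        SpeciesParams(frac_slow * n_tot, tau_slow),
    )


class TestRoundTrip:
    def test_single_2d_noiseless(self, clean_2d_curve):
        res = fit_curve(clean_2d_curve, "single_2d")
        assert res.converged
        assert res.params["n"] == pytest.approx(5.0, rel=1e-6)
        assert res.params["tau_d"] == pytest.approx(4.0, rel=1e-6)

    def test_single_3d_noiseless_fixed_a(self, lag_grid):
        curve = eval_single_3d(
            lag_grid, SpeciesParams(3.0, 6.0), ConfocalGeometry(structure_param=5.0)
        )
        res = fit_curve(curve, "single_3d", fixed={"structure_param": 5.0})
        assert res.params["n"] == pytest.approx(3.0, rel=1e-6)
        assert res.params["tau_d"] == pytest.approx(6.0, rel=1e-6)

    def test_two_species_noiseless(self, lag_grid):
        curve = eval_two_species(
            lag_grid, SpeciesParams(6.0, 2.0), SpeciesParams(4.0, 40.0)
        )
        res = fit_curve(curve, "two_species")
        assert res.converged
        assert res.params["tau_d1"] == pytest.approx(2.0, rel=1e-6)
        assert res.params["tau_d2"] == pytest.approx(40.0, rel=1e-6)
        assert res.params["n1"] == pytest.approx(6.0, rel=1e-5)
        assert res.params["n2"] == pytest.approx(4.0, rel=1e-5)
        # species reported in ascending tau_d order
        assert res.params["tau_d1"] < res.params["tau_d2"]

    def test_weighted_fit_matches_truth_on_noiseless_curve(self, lag_grid):
        clean = eval_single_2d(lag_grid, SpeciesParams(5.0, 4.0))
        sd = np.full_like(clean.values, 1e-3)
        curve = CorrelationCurve(clean.lags, clean.values, sd=sd)
        res = fit_curve(curve, weighted=True)
        assert res.params["tau_d"] == pytest.approx(4.0, rel=1e-6)


class TestMixtureFits:
    def test_apparent_tau_d_of_paper_mixture(self):
        """A 60/40 mixture of 4 ms and 15 ms species, fit with the
        single-species model, reads out ~6 ms."""
        res = fit_curve(mixture_curve(0.40), "single_2d", fit_range=None)
        assert res.params["tau_d"] == pytest.approx(6.0, abs=1.0)

    def test_apparent_tau_d_between_components(self):
        for f in (0.1, 0.5, 0.9):
            res = fit_curve(mixture_curve(f), "single_2d", fit_range=None)
            assert 4.0 < res.params["tau_d"] < 15.0

    def test_apparent_tau_d_monotone_in_slow_fraction(self):
        fracs = np.arange(0.0, 1.01, 0.1)
        taus = []
        for f in fracs:
            if f == 0.0:
                c = eval_single_2d(default_lag_grid(1e-2, 1e3, 200),
                                   SpeciesParams(1.0, 4.0))
            elif f == 1.0:
                c = eval_single_2d(default_lag_grid(1e-2, 1e3, 200),
                                   SpeciesParams(1.0, 15.0))
            else:
                c = mixture_curve(f)
            taus.append(fit_curve(c, "single_2d", fit_range=None).params["tau_d"])
        assert np.all(np.diff(taus) > 0)
        assert taus[0] == pytest.approx(4.0, rel=1e-6)
        assert taus[-1] == pytest.approx(15.0, rel=1e-6)


class TestNoisyRecovery:
    def test_mean_recovered_tau_d_unbiased(self):
        """Over 100 seeded noisy curves (sd 0.5% of G(0)), the mean fitted
        tau_d lands within 2% of the truth."""
        taus = []
        for seed in range(1, 101):
            curve = gen_curve(
                SpeciesParams(5.0, 4.0),
                noise=CurveNoiseSpec(sigma0=0.005, seed=seed),
                lag_grid=(1e-2, 1e3, 200),
            )
            res = fit_curve(curve)
            assert res.converged
            taus.append(res.params["tau_d"])
        assert np.mean(taus) == pytest.approx(4.0, rel=0.02)


class TestRefit3D:
    def test_refit_increases_tau_d_by_at_most_five_percent(self, clean_2d_curve):
        base = fit_curve(clean_2d_curve, "single_2d")
        res = refit_3d_fixed_a(clean_2d_curve, base, structure_param=7.0)
        change = res.meta["tau_d_rel_change"]
        assert 0.0 < change <= 0.05

    def test_refit_change_is_scale_invariant(self):
        """Only A and the grid-to-tau_d ratio matter: shifting tau_d and the
        lag grid by the same factor leaves the relative change unchanged."""
        changes = []
        for tau_d, lo, hi in [(2.0, 0.5e-2, 0.5e3), (8.0, 2e-2, 2e3)]:
            grid = default_lag_grid(lo, hi, 200)
            curve = eval_single_2d(grid, SpeciesParams(5.0, tau_d))
            base = fit_curve(curve, "single_2d", fit_range=None)
            res = fit_curve(
                curve, "single_3d", fixed={"structure_param": 7.0},
                init=SpeciesParams(base.params["n"], base.params["tau_d"]),
                fit_range=None,
            )
            changes.append(res.params["tau_d"] / tau_d - 1.0)
        assert changes[0] == pytest.approx(changes[1], rel=1e-4, abs=1e-6)

    def test_refit_with_huge_a_changes_nothing(self, clean_2d_curve):
        base = fit_curve(clean_2d_curve, "single_2d")
        res = refit_3d_fixed_a(clean_2d_curve, base, structure_param=1e6)
        assert abs(res.meta["tau_d_rel_change"]) < 1e-6

    def test_refit_requires_converged_2d_base(self, clean_2d_curve):
        base = fit_curve(clean_2d_curve, "single_2d")
        base.model_id = "single_3d"
        with pytest.raises(ConfigurationError):
            refit_3d_fixed_a(clean_2d_curve, base)


class TestInitHeuristic:
    def test_recovers_truth_on_noiseless_curve(self):
        grid = default_lag_grid(1e-3, 1e4, 300)
        curve = eval_single_2d(grid, SpeciesParams(10.0, 4.0))
        init = init_heuristic(curve)
        assert init.n == pytest.approx(10.0, rel=1e-2)
        assert init.tau_d == pytest.approx(4.0, rel=0.05)

    def test_increasing_curve_rejected(self):
        lags = np.linspace(1.0, 10.0, 20)
        with pytest.raises(DomainError):
            init_heuristic(CorrelationCurve(lags, np.linspace(0.1, 0.2, 20)))

    def test_flat_ish_curve_falls_back_to_last_lag(self):
        lags = np.linspace(1.0, 10.0, 20)
        values = np.linspace(0.1, 0.099, 20)  # never reaches half amplitude
        with pytest.warns(UserWarning, match="half amplitude"):
            init = init_heuristic(CorrelationCurve(lags, values))
        assert init.tau_d == pytest.approx(10.0)


class TestFitErrors:
    def test_constant_curve_is_fit_error(self):
        lags = default_lag_grid(1e-2, 1e3, 50)
        with pytest.raises(FitError, match="constant"):
            fit_curve(CorrelationCurve(lags, np.full(50, 0.1)))

    def test_too_few_lags_rejected(self):
        lags = np.linspace(1.0, 2.0, 5)
        curve = CorrelationCurve(lags, 1.0 / (1.0 + lags / 4.0))
        with pytest.raises(FitError):
            fit_curve(curve, fit_range=None)

    def test_unknown_model_rejected(self, clean_2d_curve):
        with pytest.raises(ConfigurationError):
            fit_curve(clean_2d_curve, "triplet")

    def test_weighted_fit_without_sd_rejected(self, clean_2d_curve):
        with pytest.raises(ConfigurationError):
            fit_curve(clean_2d_curve, weighted=True)
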