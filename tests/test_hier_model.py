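import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import fishdyn as fd
from fishdyn.covariates import CovariatePanel
from fishdyn.hier_model import FAMILIES, N_FAM, SiteParams

from conftest import flat_panel, params_from_dict, zero_covariates


def _status(site_id, observed, nonnull=None):
    years = 2000 + np.arange(len(observed))
    nonnull = nonnull if nonnull is not None else observed
    return pd.DataFrame({"site_id": site_id, "year": years,
                         "observed": observed, "nonnull": nonnull})


class TestFilterTimeSeries:
    def test_too_few_years_rejected(self):
        report = fd.filter_time_series(_status("a", [True] * 14))
        assert not report.loc[0, "retained"]
        assert "14 observed years" in report.loc[0, "reason"]

    def test_low_nonnull_fraction_rejected(self):
        report = fd.filter_time_series(
            _status("a", [True] * 20, [True] * 8 + [False] * 12))
        assert not report.loc[0, "retained"]
        assert "non-null" in report.loc[0, "reason"]

    def test_eligible_series_retained(self):
        observed = [True] * 8 + [False, False] + [True] * 8  # gap of 2, 16 obs
        report = fd.filter_time_series(_status("a", observed))
        assert report.loc[0, "retained"]

    def test_long_gap_rejected(self):
        observed = [True] * 10 + [False] * 4 + [True] * 16
        report = fd.filter_time_series(_status("a", observed))
        assert not report.loc[0, "retained"]
        assert "consecutive" in report.loc[0, "reason"]


class TestModelSpec:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        n, T = 2, 5
        panel = flat_panel(rng.normal(5, 1, (n, T)), rng.normal(4, 1, (n, T)),
                           rng.uniform(100, 500, (n, T)))
        U = CovariatePanel(values=rng.normal(0, 1, (4, n, T)),
                           site_ids=panel.site_ids, years=panel.years)
        params = SiteParams(values=rng.normal(0, 0.5, (n, N_FAM)))
        return panel, U, params

    def test_lambda_matches_brute_force_recomputation(self):
        panel, U, params = self._toy()
        model = fd.build_model(panel, U)
        lam0, lam1 = model.expected_log_abundance(params)
        th = params.values
        for i in range(2):
            for t in range(5):
                L = math.log(panel.S[i, t])
                expect0 = th[i, 0] + th[i, 1] * panel.X1[i, t] / L + L
                for j in range(4):
                    expect0 += th[i, 2 + j] * U.values[j, i, t]
                assert lam0[i, t] == pytest.approx(expect0, abs=1e-10)
                if t >= 1:
                    Lp = math.log(panel.S[i, t - 1])
                    expect1 = (th[i, 6] + panel.X1[i, t - 1]
                               + th[i, 7] * panel.X1[i, t - 1] / Lp
                               + th[i, 8] * panel.X0[i, t - 1] / Lp
                               + math.log(panel.S[i, t] / panel.S[i, t - 1]))
                    for j in range(4):
                        expect1 += th[i, 9 + j] * U.values[j, i, t]
                    assert lam1[i, t] == pytest.approx(expect1, abs=1e-10)

    def test_log_likelihood_matches_normal_density_sums(self):
        panel, U, params = self._toy(seed=1)
        model = fd.build_model(panel, U)
        lam0, lam1 = model.expected_log_abundance(params)
        expected = (norm.logpdf(panel.X0, lam0, 0.4).sum()
                    + norm.logpdf(panel.X1[:, 1:], lam1[:, 1:], 0.3).sum())
        assert model.log_likelihood(params, 0.4, 0.3) == pytest.approx(
            expected, abs=1e-8)

    def test_likelihood_peaks_at_generating_trajectory(self):
        # noise-free simulation: the likelihood at truth beats any perturbation
        params = params_from_dict(1, alpha1=1.0, beta1=-0.5, alpha0=0.5, beta0=1.0)
        panel = fd.simulate_abundances(params, zero_covariates(1, 8), np.e, 8,
                                       2.0, (0.0, 0.0), seed=0)
        model = fd.build_model(panel, zero_covariates(1, 8))
        best = model.log_likelihood(params, 0.1, 0.1)
        worse = params.values.copy()
        worse[:, FAMILIES.index("alpha1")] += 0.2
        assert best > model.log_likelihood(SiteParams(values=worse), 0.1, 0.1)

    def test_algebraic_reduction_constant_area_zero_covariates(self):
        rng = np.random.default_rng(3)
        panel = flat_panel(rng.normal(5, 1, (1, 6)), rng.normal(4, 1, (1, 6)),
                           float(np.exp(3.0)))
        params = params_from_dict(1, alpha1=0.7, beta1=-0.4, delta1=0.2)
        model = fd.build_model(panel, zero_covariates(1, 6))
        _, lam1 = model.expected_log_abundance(params)
        reduced = (0.7 + panel.X1[:, :-1] * (1 - 0.4 / 3.0)
                   + 0.2 * panel.X0[:, :-1] / 3.0)
        assert np.allclose(lam1[:, 1:], reduced, atol=1e-12)

    def test_misaligned_panels_rejected(self):
        panel, U, _ = self._toy()
        bad_U = CovariatePanel(values=np.zeros((4, 3, 5)),
                               site_ids=["a", "b", "c"], years=panel.years)
        with pytest.raises(ValueError):
            fd.build_model(panel, bad_U)


class TestGelmanRubin:
    def _draws(self, chains_arrays):
        arr = np.stack(chains_arrays)[:, :, None]
        chains, n = arr.shape[0], arr.shape[1]
        return fd.PosteriorDraws(
            mu=np.tile(arr, (1, 1, N_FAM)), sigma=np.abs(np.tile(arr, (1, 1, N_FAM))),
            process_sd=np.abs(np.tile(arr, (1, 1, 2))) + 0.1,
            theta=np.zeros((chains, n, 1, N_FAM)))

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = self._draws([rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)])
        r = fd.gelman_rubin(draws)
        assert (r > 0.999).all() and (r < 1.01).all()

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = self._draws([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert (fd.gelman_rubin(draws) > 10).all()

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(2)
        draws = self._draws([rng.normal(0, 1, 100)])
        with pytest.raises(ValueError):
            fd.gelman_rubin(draws)


class TestHpdInterval:
    def test_point_mass(self):
        assert fd.hpd_interval(np.full(100, 3.5)) == (3.5, 3.5)

    def test_standard_normal_endpoints(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = fd.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_interval_length(self):
        x = np.random.default_rng(1).uniform(0, 1, 200_000)
        lo, hi = fd.hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(2).normal(3, 2, 50_000)
        lo, hi = fd.hpd_interval(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)

    def test_invalid_prob_rejected(self):
        with pytest.raises(ValueError):
            fd.hpd_interval([1.0, 2.0], prob=1.5)


class TestPosteriorOverlap:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(0, 1, 5000)
        assert fd.posterior_overlap(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_samples(self):
        rng = np.random.default_rng(1)
        assert fd.posterior_overlap(rng.normal(0, 1, 5000),
                                    rng.normal(100, 1, 5000)) < 1e-6

    def test_unit_shift_closed_form(self):
        # overlap of N(0,1) and N(1,1) is 2*Phi(-1/2)
        rng = np.random.default_rng(2)
        ov = fd.posterior_overlap(rng.normal(0, 1, 200_000),
                                  rng.normal(1, 1, 200_000))
        assert ov == pytest.approx(2 * norm.cdf(-0.5), abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fd.posterior_overlap([], [1.0])


class TestFit:
    def test_chain_geometry_and_determinism(self, small_model):
        kw = dict(chains=2, iterations=300, burn_in=100, thin=5, seed=9)
        a = fd.fit(small_model, **kw)
        b = fd.fit(small_model, **kw)
        assert a.mu.shape == (2, 40, N_FAM)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.theta, b.theta)

    def test_recovers_hyper_means(self, small_study, small_draws):
        truth = small_study["truth"]
        s = small_draws.summary()
        covered = 0
        for _, row in s[s["parameter"].str.startswith("mu_")].iterrows():
            tv = truth.hyper_means[row["parameter"][3:]]
            covered += row["hpd_low"] <= tv <= row["hpd_high"]
        assert covered >= 9  # of 13 families, short-chain sanity bound

    def test_mixing_diagnostics(self, small_draws):
        assert fd.gelman_rubin(small_draws).max() < 1.2

    def test_invalid_geometry_rejected(self, small_model):
        with pytest.raises(ValueError):
            fd.fit(small_model, chains=0)
        with pytest.raises(ValueError):
            fd.fit(small_model, iterations=100, burn_in=200)

    def test_shrinkage_with_tight_sd_prior(self, small_study):
        model_loose = fd.build_model(small_study["panel"], small_study["U"],
                                     cauchy_scale=2.5)
        model_tight = fd.build_model(small_study["panel"], small_study["U"],
                                     cauchy_scale=1e-3)
        kw = dict(chains=1, iterations=400, burn_in=200, thin=4, seed=2)
        spread_loose = fd.fit(model_loose, **kw).site_medians().values.std(axis=0)
        spread_tight = fd.fit(model_tight, **kw).site_medians().values.std(axis=0)
        assert spread_tight.mean() < spread_loose.mean()


class TestPosteriorPredictiveCheck:
    def test_calibrated_under_true_model(self, small_draws, small_model):
        ppc = fd.posterior_predictive_check(small_draws, small_model, seed=0)
        assert 0.2 < ppc["p_0plus"] < 0.8
        assert 0.2 < ppc["p_oldplus"] < 0.8

    def test_detects_inflated_noise(self, small_study, small_draws):
        panel = small_study["panel"]
        rng = np.random.default_rng(0)
        noisy = fd.AbundancePanel(
            X0=panel.X0 + rng.normal(0, 3.0, panel.X0.shape),
            X1=panel.X1 + rng.normal(0, 3.0, panel.X1.shape),
            S=panel.S, mask=panel.mask, site_ids=panel.site_ids,
            years=panel.years)
        model = fd.build_model(noisy, small_study["U"])
        ppc = fd.posterior_predictive_check(small_draws, model, seed=0)
        assert ppc["p_0plus"] < 0.05 or ppc["p_0plus"] > 0.95
        assert ppc["p_oldplus"] < 0.05 or ppc["p_oldplus"] > 0.95

    def test_requires_draws(self, small_draws, small_model):
        empty = fd.PosteriorDraws(mu=small_draws.mu[:, :0], sigma=small_draws.sigma[:, :0],
                                  process_sd=small_draws.process_sd[:, :0],
                                  theta=small_draws.theta[:, :0])
        with pytest.raises(ValueError):
            fd.posterior_predictive_check(empty, small_model)
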