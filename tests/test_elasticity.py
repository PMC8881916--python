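import numpy as np
import pandas as pd
import pytest

import fishdyn as fd
from fishdyn.covariates import CovariatePanel
from fishdyn.hier_model import N_FAM, SiteParams

from conftest import flat_panel, params_from_dict, zero_covariates


def _alpha1_setup(alpha1=0.5, x_init=2.0, T=10):
    """Only the >0+ productivity rate is non-zero; area constant at e."""
    params = params_from_dict(1, alpha1=alpha1)
    panel = flat_panel(np.zeros((1, T)), np.full((1, T), x_init), np.e)
    return params, panel, zero_covariates(1, T)


class TestProjection:
    def test_all_zero_coefficients_constant_path(self):
        params = params_from_dict(1)
        panel = flat_panel(np.zeros((1, 6)), np.full((1, 6), 3.0), np.e)
        _, th1 = fd.project_abundance(params, panel, zero_covariates(1, 6))
        assert np.allclose(th1, 3.0)

    def test_alpha1_only_linear_path(self):
        params, panel, U = _alpha1_setup(alpha1=0.4, x_init=2.0, T=8)
        _, th1 = fd.project_abundance(params, panel, U, focal="alpha1")
        assert np.allclose(th1[0], 2.0 + 0.4 * np.arange(8))

    def test_matches_hand_unrolled_oracle(self):
        rng = np.random.default_rng(5)
        n, T = 2, 6
        panel = flat_panel(rng.normal(5, 1, (n, T)), rng.normal(4, 1, (n, T)),
                           rng.uniform(50, 400, (n, T)))
        U = CovariatePanel(values=rng.normal(0, 1, (4, n, T)),
                           site_ids=panel.site_ids, years=panel.years)
        params = SiteParams(values=rng.normal(0, 0.3, (n, N_FAM)))
        th0, th1 = fd.project_abundance(params, panel, U, focal="beta1")

        L = np.log(panel.S)
        for i in range(n):
            r1_obs = panel.X1[i] / L[i]
            r0_avg = (panel.X1[i] / L[i]).mean()
            rd_avg = (panel.X0[i] / L[i]).mean()
            u_avg = U.values[:, i, :].mean(axis=1)
            a0, b0 = params.values[i, 0], params.values[i, 1]
            g0 = params.values[i, 2:6]
            a1, b1, d1 = params.values[i, 6], params.values[i, 7], params.values[i, 8]
            g1 = params.values[i, 9:13]
            x = panel.X1[i, 0]
            for t in range(1, T):
                x = (a1 + x + b1 * r1_obs[t - 1] + d1 * rd_avg + g1 @ u_avg
                     + L[i, t] - L[i, t - 1])
                assert th1[i, t] == pytest.approx(x, abs=1e-10)
            for t in range(T):
                expect0 = a0 + b0 * r0_avg + g0 @ u_avg + L[i, t]
                assert th0[i, t] == pytest.approx(expect0, abs=1e-10)

    def test_unknown_family_rejected(self):
        params, panel, U = _alpha1_setup()
        with pytest.raises(ValueError):
            fd.project_abundance(params, panel, U, focal="unknown")


class TestComputeElasticity:
    def test_identical_projections_give_zero(self):
        th = np.random.default_rng(0).normal(3, 1, (2, 5))
        assert np.all(fd.compute_elasticity(th, th.copy()) == 0.0)

    def test_alpha1_closed_form(self):
        # e_t = alpha1 * t / (x_init + alpha1 * t)
        alpha1, x_init = 0.5, 2.0
        params, panel, U = _alpha1_setup(alpha1, x_init)
        _, ori = fd.project_abundance(params, panel, U, focal="alpha1")
        _, per = fd.perturb_and_project(params, panel, U, "alpha1", 0.10)
        e = fd.compute_elasticity(ori, per, 0.10)
        t = np.arange(10)
        expected = alpha1 * t / (x_init + alpha1 * t)
        assert np.allclose(e[0], expected, atol=1e-9)

    def test_alpha1_zero_start_gives_unit_elasticity(self):
        params, panel, U = _alpha1_setup(alpha1=0.5, x_init=0.0)
        _, ori = fd.project_abundance(params, panel, U, focal="alpha1")
        _, per = fd.perturb_and_project(params, panel, U, "alpha1", 0.10)
        e = fd.compute_elasticity(ori, per, 0.10)
        assert np.isnan(e[0, 0])  # theta_ori = 0 excluded
        assert np.allclose(e[0, 1:], 1.0, atol=1e-9)

    def test_zero_perturbation_rejected(self):
        with pytest.raises(ValueError):
            fd.compute_elasticity(np.ones((1, 2)), np.ones((1, 2)), 0.0)


class TestPerturbAndProject:
    def test_zero_coefficient_family_is_inert(self):
        params, panel, U = _alpha1_setup()
        _, ori = fd.project_abundance(params, panel, U, focal="beta1")
        _, per = fd.perturb_and_project(params, panel, U, "beta1", 0.10)
        assert np.array_equal(ori, per)

    def test_temperature_family_moves_linear_and_quadratic_jointly(self):
        rng = np.random.default_rng(1)
        n, T = 1, 6
        panel = flat_panel(rng.normal(5, 1, (n, T)), rng.normal(4, 1, (n, T)), 200.0)
        U = CovariatePanel(values=rng.normal(0, 1, (4, n, T)),
                           site_ids=panel.site_ids, years=panel.years)
        params = params_from_dict(n, alpha1=0.5, g1_tmean=0.3, g1_tmean2=-0.2)
        _, joint = fd.perturb_and_project(params, panel, U, "tmean1", 0.10)
        linear_only = params.values.copy()
        linear_only[:, 9] *= 1.1  # perturb only the linear term by hand
        _, partial = fd.project_abundance(SiteParams(values=linear_only),
                                          panel, U, focal="tmean1")
        assert not np.allclose(joint, partial)

    def test_first_order_consistency_in_delta(self):
        params, panel, U = _alpha1_setup(alpha1=0.5, x_init=5.0)
        e = {}
        for delta in (0.10, 0.05):
            _, ori = fd.project_abundance(params, panel, U, focal="alpha1")
            _, per = fd.perturb_and_project(params, panel, U, "alpha1", delta)
            e[delta] = fd.compute_elasticity(ori, per, delta)[0, 1:]
        assert np.max(np.abs(e[0.05] / e[0.10] - 1.0)) < 0.01

    def test_unknown_family_rejected(self):
        params, panel, U = _alpha1_setup()
        with pytest.raises(ValueError):
            fd.perturb_and_project(params, panel, U, "unknown")


class TestElasticityAnalysis:
    def test_species_mean_is_mean_of_used_points(self):
        rng = np.random.default_rng(2)
        n, T = 3, 8
        panel = flat_panel(rng.normal(5, 1, (n, T)), rng.normal(4, 1, (n, T)),
                           rng.uniform(50, 400, (n, T)))
        U = CovariatePanel(values=rng.normal(0, 1, (4, n, T)),
                           site_ids=panel.site_ids, years=panel.years)
        params = SiteParams(values=rng.normal(0, 0.3, (n, N_FAM)))
        res = fd.elasticity_analysis(params, panel, U)
        for omega, arr in res.e.items():
            assert res.species_mean[omega] == pytest.approx(np.nanmean(arr))
        assert set(res.site_mean["omega"]) == set(res.e)


class TestCompareSpecies:
    def _means(self, values, sites=None):
        sites = sites or [f"s{i}" for i in range(len(values))]
        return pd.DataFrame({"omega": "beta1", "site_id": sites, "value": values})

    def test_identical_distributions_not_significant(self):
        v = list(np.random.default_rng(0).normal(0, 1, 20))
        out = fd.compare_species({"a": self._means(v), "b": self._means(v)})
        assert out.loc[0, "p_adjusted"] == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 50)
        out = fd.compare_species({"a": self._means(list(v)),
                                  "b": self._means(list(v + 10))})
        assert out.loc[0, "p_adjusted"] < 0.001
        assert out.loc[0, "test"] == "wilcoxon"

    def test_disjoint_sites_fall_back_to_ranksum(self):
        rng = np.random.default_rng(2)
        a = self._means(list(rng.normal(0, 1, 30)), [f"a{i}" for i in range(30)])
        b = self._means(list(rng.normal(5, 1, 30)), [f"b{i}" for i in range(30)])
        out = fd.compare_species({"a": a, "b": b})
        assert out.loc[0, "test"] == "ranksum"
        assert out.loc[0, "p_adjusted"] < 0.001

    def test_too_few_shared_sites_skipped(self):
        a = self._means([1.0, 2.0, 3.0], ["s1", "s2", "s3"])
        b = self._means([1.5, 2.5, 9.0], ["s1", "s2", "x9"])
        out = fd.compare_species({"a": a, "b": b})
        assert pd.isna(out.loc[0, "p_raw"])
        assert "shared sites" in out.loc[0, "reason"]
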