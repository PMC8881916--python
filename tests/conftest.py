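import numpy as np
import pytest

import fishdyn as fd
from fishdyn.covariates import CovariatePanel
from fishdyn.hier_model import FAMILIES, N_FAM, AbundancePanel, SiteParams


def zero_covariates(n_sites, n_years, site_ids=None):
    """A covariate panel with every temperature entry at the pooled mean."""
    return CovariatePanel(
        values=np.zeros((4, n_sites, n_years)),
        site_ids=site_ids or [f"S{i:03d}" for i in range(n_sites)],
        years=list(range(2000, 2000 + n_years)),
    )


def params_from_dict(n_sites, **kwargs) -> SiteParams:
    """Site coefficients all zero except the named families (shared across sites)."""
    values = np.zeros((n_sites, N_FAM))
    for fam, v in kwargs.items():
        values[:, FAMILIES.index(fam)] = v
    return SiteParams(values=values)


def flat_panel(X0, X1, S, mask=None) -> AbundancePanel:
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    S = np.broadcast_to(np.asarray(S, dtype=float), X0.shape)
    if mask is None:
        mask = np.ones(X0.shape, dtype=bool)
    return AbundancePanel(X0=X0, X1=X1, S=S, mask=mask,
                          site_ids=[f"S{i:03d}" for i in range(X0.shape[0])],
                          years=list(range(2000, 2000 + X0.shape[1])))


@pytest.fixture(scope="session")
def small_study():
    """10 sites x 15 years with 10% missing interior years."""
    return fd.make_study(n_sites=10, n_years=15, seed=3, missing_fraction=0.1)


@pytest.fixture(scope="session")
def small_model(small_study):
    return fd.build_model(small_study["panel"], small_study["U"])


@pytest.fixture(scope="session")
def small_draws(small_model):
    """A short but usable posterior for diagnostics and downstream stages."""
    return fd.fit(small_model, chains=2, iterations=1500, burn_in=300, thin=6,
                  seed=1)
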