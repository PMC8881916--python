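"""Numerical elasticity analysis of the fitted population model.

Posterior-median coefficients are used to project log-abundance of both size
classes deterministically over the study period.  For each parameter family
the projection is repeated with the family's coefficients increased
proportionally (default 10%; linear and quadratic temperature terms move
together) and the elasticity is the relative change of the projected
log-abundance per unit relative change of the parameter::

    e[w, i, t] = (theta_per[i, t] - theta_ori[i, t]) / theta_ori[i, t] / delta

Predictor policy: the focal family's predictor takes its observed site-year
values, every other predictor is held at its site-level time average; the
carried-over >0+ state is the projected value (fully iterative trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .hier_model import FAMILIES, AbundancePanel, SiteParams, _interpolate_missing

#: elasticity families: coefficient columns perturbed together and the size
#: class whose projected log-abundance they act on (0 = young-of-year)
OMEGA_FAMILIES: dict[str, tuple[tuple[str, ...], int]] = {
    "alpha0": (("alpha0",), 0),
    "beta0": (("beta0",), 0),
    "tmean0": (("g0_tmean", "g0_tmean2"), 0),
    "tvar0": (("g0_tvar", "g0_tvar2"), 0),
    "alpha1": (("alpha1",), 1),
    "beta1": (("beta1",), 1),
    "delta1": (("delta1",), 1),
    "tmean1": (("g1_tmean", "g1_tmean2"), 1),
    "tvar1": (("g1_tvar", "g1_tvar2"), 1),
}

#: the eight families analysed in the spatial-model-selection stage
DEFAULT_OMEGAS = ("tmean0", "tvar0", "tmean1", "tvar1",
                  "alpha1", "beta0", "beta1", "delta1")


@dataclass
class ElasticityResult:
    e: dict                      # omega -> (n_sites, n_years) array (NaN = excluded)
    site_mean: pd.DataFrame      # columns: omega, site_id, value
    species_mean: dict           # omega -> float
    perturb_fraction: float
    excluded_points: list = field(default_factory=list)  # (omega, site, year)


def _predictors(panel: AbundancePanel, U) -> dict:
    """Observed and site-averaged predictor values used by the projection."""
    L = panel.log_area()
    X0 = _interpolate_missing(panel.X0, panel.mask)
    X1 = _interpolate_missing(panel.X1, panel.mask)
    r0 = X1 / L                    # recruitment predictor (same-year)
    r1 = X1 / L                    # density-dependence predictor (lagged in use)
    rd = X0 / L                    # transition predictor (lagged in use)
    obs = panel.mask

    def site_avg(arr):
        out = np.empty(arr.shape[0])
        for i in range(arr.shape[0]):
            vals = arr[i][obs[i]] if obs[i].any() else arr[i]
            out[i] = vals.mean()
        return out[:, None]

    Uv = U.values
    return {
        "L": L, "X1": X1,
        "r0": r0, "r0_avg": site_avg(r0),
        "r1": r1, "r1_avg": site_avg(r1),
        "rd": rd, "rd_avg": site_avg(rd),
        "U": Uv, "U_avg": np.stack([site_avg(Uv[j]) for j in range(Uv.shape[0])]),
    }


_U_INDEX = {"g0_tmean": 0, "g0_tmean2": 1, "g0_tvar": 2, "g0_tvar2": 3,
            "g1_tmean": 0, "g1_tmean2": 1, "g1_tvar": 2, "g1_tvar2": 3}


def project_abundance(medians: SiteParams, panel: AbundancePanel, U,
                      focal: str = None, mode: str = "iterative"):
    """Deterministic projection of (theta0, theta1) log-abundance paths.

    ``focal`` names the elasticity family whose predictors take observed
    values (all others are site-time averages); ``None`` averages everything.
    ``mode='iterative'`` feeds the projected >0+ state back into the
    recursion; ``mode='one-step'`` uses the observed state at t-1 instead.
    """
    if focal is not None and focal not in OMEGA_FAMILIES:
        raise ValueError(f"unknown parameter family: {focal}")
    if mode not in ("iterative", "one-step"):
        raise ValueError("mode must be 'iterative' or 'one-step'")
    pr = _predictors(panel, U)
    th = medians.values
    n, T = panel.X0.shape
    if T < 2:
        raise ValueError("projection needs at least 2 years")
    L = pr["L"]
    a0, b0 = th[:, 0], th[:, 1]
    g0 = th[:, 2:6]
    a1, b1, d1 = th[:, 6], th[:, 7], th[:, 8]
    g1 = th[:, 9:13]

    focal_cols = OMEGA_FAMILIES[focal][0] if focal else ()
    p_r0 = pr["r0"] if "beta0" in focal_cols else np.broadcast_to(pr["r0_avg"], (n, T))
    p_r1 = pr["r1"] if "beta1" in focal_cols else np.broadcast_to(pr["r1_avg"], (n, T))
    p_rd = pr["rd"] if "delta1" in focal_cols else np.broadcast_to(pr["rd_avg"], (n, T))
    U_use0 = np.empty((4, n, T))
    U_use1 = np.empty((4, n, T))
    for name, j in (("tmean", 0), ("tmean2", 1), ("tvar", 2), ("tvar2", 3)):
        obs_vals = pr["U"][j]
        avg_vals = np.broadcast_to(pr["U_avg"][j], (n, T))
        U_use0[j] = obs_vals if f"g0_{name}" in focal_cols else avg_vals
        U_use1[j] = obs_vals if f"g1_{name}" in focal_cols else avg_vals

    theta0 = np.empty((n, T))
    theta1 = np.empty((n, T))
    theta1[:, 0] = pr["X1"][:, 0]
    for t in range(1, T):
        carry = theta1[:, t - 1] if mode == "iterative" else pr["X1"][:, t - 1]
        theta1[:, t] = (a1 + carry + b1 * p_r1[:, t - 1] + d1 * p_rd[:, t - 1]
                        + np.einsum("ij,ji->i", g1, U_use1[:, :, t])
                        + L[:, t] - L[:, t - 1])
    for t in range(T):
        theta0[:, t] = (a0 + b0 * p_r0[:, t]
                        + np.einsum("ij,ji->i", g0, U_use0[:, :, t]) + L[:, t])
    return theta0, theta1


def perturb_and_project(medians: SiteParams, panel: AbundancePanel, U,
                        omega: str, perturb_fraction: float = 0.10,
                        mode: str = "iterative"):
    """Re-run the projection with the focal family scaled by (1 + delta).

    Linear and quadratic temperature coefficients are perturbed together.
    """
    if omega not in OMEGA_FAMILIES:
        raise ValueError(f"unknown parameter family: {omega}")
    cols, _ = OMEGA_FAMILIES[omega]
    values = medians.values.copy()
    for col in cols:
        values[:, FAMILIES.index(col)] *= (1.0 + perturb_fraction)
    perturbed = SiteParams(values=values, site_ids=medians.site_ids)
    return project_abundance(perturbed, panel, U, focal=omega, mode=mode)


def compute_elasticity(theta_ori: np.ndarray, theta_per: np.ndarray,
                       perturb_fraction: float = 0.10,
                       eps: float = 1e-6) -> np.ndarray:
    """Pointwise numerical elasticity; |theta_ori| < eps points become NaN."""
    if perturb_fraction == 0:
        raise ValueError("perturb_fraction must be non-zero")
    theta_ori = np.asarray(theta_ori, dtype=float)
    theta_per = np.asarray(theta_per, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (theta_per - theta_ori) / theta_ori / perturb_fraction
    e[np.abs(theta_ori) < eps] = np.nan
    return e


def elasticity_analysis(medians: SiteParams, panel: AbundancePanel, U,
                        omegas=DEFAULT_OMEGAS, perturb_fraction: float = 0.10,
                        mode: str = "iterative") -> ElasticityResult:
    """Full elasticity table: per site-year values, site means, species means."""
    e_all = {}
    excluded = []
    rows = []
    species_mean = {}
    site_ids = panel.site_ids
    for omega in omegas:
        _, cls = OMEGA_FAMILIES[omega]
        ori = project_abundance(medians, panel, U, focal=omega, mode=mode)[cls]
        per = perturb_and_project(medians, panel, U, omega,
                                  perturb_fraction, mode=mode)[cls]
        e = compute_elasticity(ori, per, perturb_fraction)
        e_all[omega] = e
        for i, t in zip(*np.nonzero(~np.isfinite(e))):
            excluded.append((omega, site_ids[i], panel.years[t]))
        site_vals = np.nanmean(e, axis=1)
        for i, site in enumerate(site_ids):
            rows.append({"omega": omega, "site_id": site, "value": site_vals[i]})
        species_mean[omega] = float(np.nanmean(e))
    return ElasticityResult(e=e_all, site_mean=pd.DataFrame(rows),
                            species_mean=species_mean,
                            perturb_fraction=perturb_fraction,
                            excluded_points=excluded)


def compare_species(site_means: dict, min_paired: int = 6,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise between-species tests of site-level elasticities.

    ``site_means`` maps species name -> DataFrame (omega, site_id, value).
    Shared sites (>= ``min_paired``) get a Wilcoxon signed-rank test; fully
    disjoint site sets fall back to a rank-sum test; anything else is skipped
    with a reason.  p-values are Bonferroni-adjusted over all tests run.
    """
    species = sorted(site_means)
    if len(species) < 2:
        raise ValueError("need at least two species to compare")
    rows = []
    for a_i in range(len(species)):
        for b_i in range(a_i + 1, len(species)):
            sa, sb = species[a_i], species[b_i]
            fa, fb = site_means[sa], site_means[sb]
            for omega in sorted(set(fa["omega"]) & set(fb["omega"])):
                va = fa[fa["omega"] == omega].set_index("site_id")["value"]
                vb = fb[fb["omega"] == omega].set_index("site_id")["value"]
                shared = va.index.intersection(vb.index)
                row = {"species_a": sa, "species_b": sb, "omega": omega,
                       "test": None, "p_raw": np.nan, "reason": ""}
                if len(shared) >= min_paired:
                    d = (va[shared] - vb[shared]).to_numpy()
                    if np.allclose(d, 0):
                        row.update(test="wilcoxon", p_raw=1.0)
                    else:
                        row.update(test="wilcoxon",
                                   p_raw=float(wilcoxon(d).pvalue))
                elif len(shared) == 0 and len(va) and len(vb):
                    row.update(test="ranksum",
                               p_raw=float(mannwhitneyu(va, vb).pvalue))
                else:
                    row["reason"] = (f"only {len(shared)} shared sites "
                                     f"(need >= {min_paired}) and sets not disjoint")
                rows.append(row)
    out = pd.DataFrame(rows)
    n_tests = int(out["p_raw"].notna().sum())
    out["p_adjusted"] = np.minimum(out["p_raw"] * max(n_tests, 1), 1.0)
    out["significant"] = out["p_adjusted"] < alpha
    return out
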