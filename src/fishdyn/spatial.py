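"""Spatial-hypothesis model selection on site-level elasticities.

For each parameter family, four ordinary least-squares models of the site
elasticities are compared by AIC: an intercept-only null, and quadratic
models in elevation, latitude (range-shift hypothesis) and great-circle
distance to the geographic range center (abundant-center hypothesis).
Covariates are z-scored before their squares are built.  AIC counts the
residual variance as a free parameter (k = intercept + slopes + 1), the
convention of R's ``AIC`` so rows are comparable with that toolchain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .errors import InsufficientDataError

CANDIDATES = ("null", "elevation", "distance", "latitude")
_COVARIATE_COL = {"elevation": "elevation", "distance": "distance_to_center",
                  "latitude": "latitude"}


@dataclass
class ModelSelectionResult:
    table: pd.DataFrame     # per family: AIC of the four candidates + best model
    coefficients: dict      # family -> {model, params, adj_r2, lrt_p}

    def best_counts(self) -> pd.Series:
        return self.table["best_model"].value_counts()


def _aic(res) -> float:
    # 2k - 2 logL with k counting intercept, slopes and the residual variance
    k = res.df_model + 1 + 1
    return float(2.0 * k - 2.0 * res.llf)


def fit_candidates(site_values: pd.DataFrame, covariates: pd.DataFrame,
                   min_sites: int = 5) -> dict:
    """Fit the four candidate models for one parameter family.

    ``site_values`` has columns ``site_id, value``; ``covariates`` columns
    ``site_id, elevation, latitude, distance_to_center``.  Returns a dict with
    per-candidate AIC, the best model's label, coefficients, adjusted R^2 and
    the likelihood-ratio p-value of the best model against the null.
    """
    merged = site_values.merge(covariates, on="site_id").dropna(
        subset=["value", "elevation", "latitude", "distance_to_center"])
    n = len(merged)
    if n < min_sites:
        raise InsufficientDataError(f"need >= {min_sites} sites, got {n}")
    y = merged["value"].to_numpy(dtype=float)

    fits = {}
    skipped = {}
    res_null = sm.OLS(y, np.ones((n, 1))).fit()
    fits["null"] = res_null
    for name in ("elevation", "distance", "latitude"):
        c = merged[_COVARIATE_COL[name]].to_numpy(dtype=float)
        sd = c.std(ddof=1)
        if sd == 0:
            skipped[name] = "covariate constant across sites"
            continue
        z = (c - c.mean()) / sd
        X = sm.add_constant(np.column_stack([z, z**2]))
        fits[name] = sm.OLS(y, X).fit()

    aics = {name: _aic(res) for name, res in fits.items()}
    # ties break toward the simpler model: null first in candidate order
    best = min(aics, key=lambda m: (round(aics[m], 10), CANDIDATES.index(m)))
    res_best = fits[best]
    extra_df = int(res_best.df_model - res_null.df_model)
    if extra_df > 0:
        lrt_stat = 2.0 * (res_best.llf - res_null.llf)
        lrt_p = float(chi2.sf(lrt_stat, extra_df))
    else:
        lrt_p = 1.0
    return {
        "aic": aics, "best_model": best,
        "coefficients": np.asarray(res_best.params).tolist(),
        "adj_r2": float(res_best.rsquared_adj),
        "lrt_p": lrt_p, "n_sites": n, "skipped": skipped,
    }


def select_best(family_results: dict) -> ModelSelectionResult:
    """Summarise per-family fits into a selection table and hypothesis tally.

    ``family_results`` maps parameter-family name -> output of
    :func:`fit_candidates`.  Elevation/latitude wins count toward the
    range-shift hypothesis, distance wins toward the abundant-center one.
    """
    if not family_results:
        raise ValueError("no model-selection results to summarise")
    rows = []
    coefficients = {}
    for fam, res in family_results.items():
        row = {"family": fam}
        for cand in CANDIDATES:
            row[f"aic_{cand}"] = res["aic"].get(cand, np.nan)
        row["best_model"] = res["best_model"]
        row["adj_r2"] = res["adj_r2"]
        row["lrt_p"] = res["lrt_p"]
        rows.append(row)
        coefficients[fam] = {"model": res["best_model"],
                             "params": res["coefficients"],
                             "adj_r2": res["adj_r2"], "lrt_p": res["lrt_p"]}
    table = pd.DataFrame(rows)
    counts = table["best_model"].value_counts()
    range_shift = int(counts.get("elevation", 0) + counts.get("latitude", 0))
    abundant_center = int(counts.get("distance", 0))
    if range_shift > abundant_center and range_shift > counts.get("null", 0):
        verdict = "range-shift"
    elif abundant_center > range_shift and abundant_center > counts.get("null", 0):
        verdict = "abundant-center"
    else:
        verdict = "none"
    table.attrs["verdict"] = verdict
    return ModelSelectionResult(table=table, coefficients=coefficients)


def run_selection(site_means: pd.DataFrame, covariates: pd.DataFrame,
                  min_sites: int = 5) -> ModelSelectionResult:
    """fit_candidates for every family in a long (omega, site_id, value) table."""
    results = {}
    for fam, grp in site_means.groupby("omega", sort=False):
        results[fam] = fit_candidates(grp[["site_id", "value"]], covariates,
                                      min_sites=min_sites)
    return select_best(results)
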