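"""Synthetic site-structured monitoring datasets with known ground truth.

Emulates the statistical structure the downstream analysis assumes: site
coefficients drawn from normal hyper distributions (optionally with an
injected spatial gradient), two-size-class log-abundance dynamics with
normal process error, two-normal length mixtures per sampling event,
elevation-correlated water temperatures, and missing-year patterns that
respect the eligibility filters.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariatePanel, U_NAMES, build_U
from .hier_model import FAMILIES, N_FAM, AbundancePanel, HyperParams, SiteParams

#: hyper means of the magnitude reported for temperate cyprinid populations:
#: productivity above 1, positive recruitment, strong negative density
#: dependence, moderate positive 0+ survival, weak and mostly-linear
#: temperature effects.
DEFAULT_HYPER_MEANS = {
    "alpha0": 1.0, "beta0": 1.5,
    "g0_tmean": 0.20, "g0_tmean2": -0.05, "g0_tvar": 0.15, "g0_tvar2": -0.05,
    "alpha1": 1.5, "beta1": -4.5, "delta1": 0.5,
    "g1_tmean": 0.10, "g1_tmean2": -0.03, "g1_tvar": 0.10, "g1_tvar2": -0.03,
}
DEFAULT_HYPER_SDS = {
    "alpha0": 0.30, "beta0": 0.30,
    "g0_tmean": 0.10, "g0_tmean2": 0.05, "g0_tvar": 0.10, "g0_tvar2": 0.05,
    "alpha1": 0.25, "beta1": 0.50, "delta1": 0.15,
    "g1_tmean": 0.08, "g1_tmean2": 0.04, "g1_tvar": 0.08, "g1_tvar2": 0.04,
}
DEFAULT_PROCESS_SDS = (0.4, 0.3)  # (0+, >0+)

#: default two-normal length mixture (mm): 0+ vs >0+ components
DEFAULT_MIXTURE = {"mean0": 60.0, "sd0": 10.0, "mean1": 180.0, "sd1": 30.0}


@dataclass
class SimulationTruth:
    """Ground-truth generating quantities for one synthetic study."""

    hyper_means: dict = field(default_factory=lambda: dict(DEFAULT_HYPER_MEANS))
    hyper_sds: dict = field(default_factory=lambda: dict(DEFAULT_HYPER_SDS))
    process_sds: tuple = DEFAULT_PROCESS_SDS
    spatial_gradient_spec: dict | None = None  # family -> (covariate, lin, quad)
    seed: int = 0
    site_params: SiteParams | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.hyper_sds.values()):
            raise ValueError("hyper SDs must be non-negative")
        if any(s < 0 for s in self.process_sds):
            raise ValueError("process SDs must be non-negative")
        missing = set(FAMILIES) - set(self.hyper_means)
        if missing:
            raise ValueError(f"hyper_means missing families: {sorted(missing)}")

    def hyper_params(self) -> HyperParams:
        return HyperParams(
            mu=np.array([self.hyper_means[f] for f in FAMILIES]),
            sigma=np.array([self.hyper_sds[f] for f in FAMILIES]),
            process_sd0=max(self.process_sds[0], 1e-12),
            process_sd1=max(self.process_sds[1], 1e-12),
        )


def generate_sites(n_sites: int, seed: int = 0,
                   lon_range=(-1.0, 7.0), lat_range=(43.0, 49.5),
                   elevation_range=(0.0, 1500.0)) -> pd.DataFrame:
    """Site metadata table: id, longitude, latitude, elevation (m)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(n_sites)],
        "longitude": rng.uniform(*lon_range, n_sites),
        "latitude": rng.uniform(*lat_range, n_sites),
        "elevation": rng.uniform(*elevation_range, n_sites),
    })


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def generate_parameters(truth: SimulationTruth, sites: pd.DataFrame) -> SiteParams:
    """Draw per-site coefficients from the hyper distributions.

    With a ``spatial_gradient_spec`` entry ``family -> (covariate, lin, quad)``
    the family's site-level mean is shifted by ``lin*z + quad*z**2`` where
    ``z`` is the z-scored site covariate (e.g. elevation), before the normal
    noise with the family's hyper SD is added.
    """
    rng = np.random.default_rng(truth.seed)
    n = len(sites)
    values = np.empty((n, N_FAM))
    grad = truth.spatial_gradient_spec or {}
    for fam, spec in grad.items():
        if fam not in FAMILIES:
            raise ValueError(f"unknown parameter family in gradient spec: {fam}")
        if spec[0] not in sites.columns:
            raise ValueError(f"gradient references unknown covariate {spec[0]!r}")
    for k, fam in enumerate(FAMILIES):
        mean = np.full(n, truth.hyper_means[fam])
        if fam in grad:
            cov, lin, quad = grad[fam]
            z = _zscore(sites[cov].to_numpy(dtype=float))
            mean = mean + lin * z + quad * z**2
        values[:, k] = mean + rng.normal(0.0, truth.hyper_sds[fam], n)
    return SiteParams(values=values, site_ids=list(sites["site_id"]))


def simulate_temperature_summaries(sites: pd.DataFrame, years, seed: int = 0,
                                   base_mean: float = 16.0,
                                   lapse_per_km: float = 5.5,
                                   base_var: float = 3.5) -> pd.DataFrame:
    """Annual water-temperature mean/variability, correlated with elevation.

    Mean temperature cools with elevation (linear lapse); intra-annual
    variability grows mildly with elevation.  Year-to-year noise makes the
    covariates informative within sites.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, site in sites.iterrows():
        elev_km = site["elevation"] / 1000.0
        for year in years:
            rows.append({
                "site_id": site["site_id"], "year": int(year),
                "t_mean": base_mean - lapse_per_km * elev_km + rng.normal(0, 1.0),
                "t_var": base_var + 1.5 * elev_km + abs(rng.normal(0, 0.4)),
            })
    return pd.DataFrame(rows)


def simulate_daily_temperatures(sites: pd.DataFrame, years, seed: int = 0,
                                base_mean: float = 16.0,
                                lapse_per_km: float = 5.5,
                                amplitude: float = 7.0) -> pd.DataFrame:
    """Daily water temperatures: seasonal sinusoid + site lapse + daily noise."""
    rng = np.random.default_rng(seed)
    frames = []
    for _, site in sites.iterrows():
        level = base_mean - lapse_per_km * site["elevation"] / 1000.0
        for year in years:
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy()
            temp = (level + amplitude * np.sin(2 * np.pi * (doy - 105) / 365.25)
                    + rng.normal(0, 0.8, doy.size))
            frames.append(pd.DataFrame({"site_id": site["site_id"], "date": dates,
                                        "temp_c": temp}))
    return pd.concat(frames, ignore_index=True)


def simulate_abundances(params: SiteParams, covariates: CovariatePanel,
                        areas: np.ndarray, T: int, x0,
                        process_sds=DEFAULT_PROCESS_SDS, seed: int = 0,
                        site_ids=None, years=None) -> AbundancePanel:
    """Simulate the two-size-class log-abundance dynamics.

    ``areas`` is (n_sites, T) sampled areas (must exceed 1 m^2 so the
    log-area density denominator is positive); ``x0`` the initial >0+
    log-abundance per site (scalar or length-n array).  The >0+ class follows
    the modified Gompertz recursion from year 2 on; the 0+ class is generated
    from the same-year recruitment equation in every year.  With zero process
    SDs the output is the deterministic recursion.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    th = params.values
    n = th.shape[0]
    areas = np.broadcast_to(np.asarray(areas, dtype=float), (n, T)).copy()
    if np.any(areas <= 1.0):
        raise ValueError("all sampled areas must exceed 1 m^2")
    U = covariates.values
    if U.shape[1] != n or U.shape[2] < T:
        raise ValueError("covariate panel misaligned with parameters/years")
    s0, s1 = process_sds
    if s0 < 0 or s1 < 0:
        raise ValueError("process SDs must be non-negative")
    rng = np.random.default_rng(seed)
    L = np.log(areas)
    a0, b0 = th[:, 0], th[:, 1]
    g0 = th[:, 2:6]
    a1, b1, d1 = th[:, 6], th[:, 7], th[:, 8]
    g1 = th[:, 9:13]

    X0 = np.empty((n, T))
    X1 = np.empty((n, T))
    X1[:, 0] = np.broadcast_to(np.asarray(x0, dtype=float), (n,))
    lam0 = (a0 + b0 * X1[:, 0] / L[:, 0]
            + np.einsum("ij,ji->i", g0, U[:, :, 0]) + L[:, 0])
    X0[:, 0] = lam0 + rng.normal(0.0, s0, n) if s0 > 0 else lam0
    for t in range(1, T):
        lam1 = (a1 + X1[:, t - 1] + b1 * X1[:, t - 1] / L[:, t - 1]
                + d1 * X0[:, t - 1] / L[:, t - 1]
                + np.einsum("ij,ji->i", g1, U[:, :, t])
                + L[:, t] - L[:, t - 1])
        X1[:, t] = lam1 + rng.normal(0.0, s1, n) if s1 > 0 else lam1
        lam0 = (a0 + b0 * X1[:, t] / L[:, t]
                + np.einsum("ij,ji->i", g0, U[:, :, t]) + L[:, t])
        X0[:, t] = lam0 + rng.normal(0.0, s0, n) if s0 > 0 else lam0

    if site_ids is None:
        site_ids = params.site_ids or [f"S{i:03d}" for i in range(n)]
    if years is None:
        years = list(range(2000, 2000 + T))
    return AbundancePanel(X0=X0, X1=X1, S=areas,
                          mask=np.ones((n, T), dtype=bool),
                          site_ids=list(site_ids), years=list(years))


def simulate_lengths(counts: pd.DataFrame, mixture: dict = None,
                     seed: int = 0) -> pd.DataFrame:
    """Per-event individual body lengths with true size-class labels.

    ``counts`` has columns ``event_id, n0, n1``; ``mixture`` supplies
    ``mean0, sd0, mean1, sd1`` (mm) with the 0+ mean strictly below the >0+
    mean.  Returns one row per individual: event_id, length_mm, true label.
    """
    mix = dict(DEFAULT_MIXTURE, **(mixture or {}))
    if mix["mean0"] <= 0 or mix["mean1"] <= 0:
        raise ValueError("component means must be positive")
    if mix["mean0"] >= mix["mean1"]:
        raise ValueError("0+ mean must be below the >0+ mean")
    if (counts[["n0", "n1"]] < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for row in counts.itertuples(index=False):
        n0, n1 = int(row.n0), int(row.n1)
        lengths = np.concatenate([
            rng.normal(mix["mean0"], mix["sd0"], n0),
            rng.normal(mix["mean1"], mix["sd1"], n1),
        ])
        labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
        frames.append(pd.DataFrame({"event_id": row.event_id,
                                    "length_mm": np.abs(lengths),
                                    "label": labels}))
    if not frames:
        return pd.DataFrame(columns=["event_id", "length_mm", "label"])
    return pd.concat(frames, ignore_index=True)


def inject_missingness(panel: AbundancePanel, missing_fraction: float,
                       max_consecutive: int = 3, seed: int = 0) -> AbundancePanel:
    """Mask random years, never the first or last, with bounded gap runs.

    Raises if the requested fraction is infeasible under the run constraint.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must lie in [0, 1)")
    if max_consecutive < 0:
        raise ValueError("max_consecutive must be >= 0")
    if missing_fraction == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    mask = panel.mask.copy()
    n, T = mask.shape
    for i in range(n):
        target = int(round(missing_fraction * T))
        interior = list(range(1, T - 1))
        rng.shuffle(interior)
        placed = 0
        for t in interior:
            if placed >= target:
                break
            mask[i, t] = False
            if _max_run(~mask[i]) > max_consecutive:
                mask[i, t] = True
            else:
                placed += 1
        if placed < target:
            raise ValueError(
                f"missing_fraction={missing_fraction} infeasible for site {i} "
                f"with max_consecutive={max_consecutive} over {T} years")
    X0, X1 = panel.X0.copy(), panel.X1.copy()
    X0[~mask] = np.nan
    X1[~mask] = np.nan
    return AbundancePanel(X0=X0, X1=X1, S=panel.S, mask=mask,
                          site_ids=panel.site_ids, years=panel.years)


def _max_run(missing_flags: np.ndarray) -> int:
    best = run = 0
    for f in missing_flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def make_study(n_sites: int = 30, n_years: int = 20, seed: int = 0,
               missing_fraction: float = 0.1, truth: SimulationTruth = None,
               spatial_gradient_spec: dict = None) -> dict:
    """One full synthetic study: sites, truth, covariates, abundance panel.

    The defaults (30 sites x 20 years, ~10% interior missing years, hyper
    values of field magnitude) produce panels that pass the eligibility
    filters, so the whole pipeline runs end to end on the output.
    """
    rng = np.random.default_rng(seed)
    sites = generate_sites(n_sites, seed=seed)
    years = list(range(1992, 1992 + n_years))
    if truth is None:
        truth = SimulationTruth(seed=int(rng.integers(2**31)),
                                spatial_gradient_spec=spatial_gradient_spec)
    params = generate_parameters(truth, sites)
    temps = simulate_temperature_summaries(sites, years,
                                           seed=int(rng.integers(2**31)))
    U = build_U(temps, site_ids=list(sites["site_id"]), years=years)
    base_area = rng.uniform(150.0, 900.0, n_sites)
    areas = base_area[:, None] * np.exp(rng.normal(0, 0.1, (n_sites, n_years)))
    x0 = rng.normal(3.0, 0.5, n_sites)
    panel = simulate_abundances(params, U, areas, n_years, x0,
                                process_sds=truth.process_sds,
                                seed=int(rng.integers(2**31)),
                                site_ids=list(sites["site_id"]), years=years)
    if missing_fraction > 0:
        panel = inject_missingness(panel, missing_fraction,
                                   seed=int(rng.integers(2**31)))
    return {"sites": sites, "truth": truth, "params": params, "U": U,
            "panel": panel, "temperature_summaries": temps, "years": years}


def write_study(study: dict, out_dir) -> dict:
    """Write a study to CSV/JSON files; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study["sites"].to_csv(out / "sites.csv", index=False)
    study["temperature_summaries"].to_csv(out / "temperature_summaries.csv", index=False)
    study["U"].to_frame().to_csv(out / "covariates.csv", index=False)

    panel = study["panel"]
    rows = []
    for i, site in enumerate(panel.site_ids):
        for t, year in enumerate(panel.years):
            rows.append({"site_id": site, "year": year,
                         "x0": panel.X0[i, t] if panel.mask[i, t] else np.nan,
                         "x1": panel.X1[i, t] if panel.mask[i, t] else np.nan,
                         "area_m2": panel.S[i, t],
                         "observed": bool(panel.mask[i, t])})
    pd.DataFrame(rows).to_csv(out / "abundance.csv", index=False)

    truth = study["truth"]
    truth_json = {
        "hyper_means": truth.hyper_means, "hyper_sds": truth.hyper_sds,
        "process_sds": list(truth.process_sds), "seed": truth.seed,
        "spatial_gradient_spec": truth.spatial_gradient_spec,
        "site_params": study["params"].values.tolist(),
        "families": list(FAMILIES),
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    manifest = {"files": sorted(p.name for p in out.iterdir()),
                "n_sites": panel.n_sites, "n_years": panel.n_years,
                "seed": truth.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
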