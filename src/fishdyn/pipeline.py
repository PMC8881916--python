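"""Pipeline orchestration: staged runs with a manifest, seeds and file hashes.

Stage order: simulate -> split_sizes -> covariates -> filter -> fit ->
elasticity -> spatial.  Each stage reads its inputs from the run directory
and writes its outputs there, so a run can be resumed or executed one stage
at a time from the command line; re-running with the same configuration
reproduces all deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import elasticity as ela
from . import hier_model as hm
from . import io as fio
from . import length_classes as lc
from . import spatial as sp
from . import synthetic as syn
from .errors import StageDependencyError

STAGES = ("simulate", "split_sizes", "covariates", "filter", "fit",
          "elasticity", "spatial")


@dataclass
class RunConfig:
    out_dir: str = "fishdyn_run"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic-study settings
    n_sites: int = 30
    n_years: int = 20
    missing_fraction: float = 0.1
    n_events: int = 40
    max_event_count: int = 250
    kappa_splits: int = 100
    # eligibility filters
    min_years: int = 15
    min_nonnull: float = 0.5
    max_gap: int = 3
    # sampler settings
    chains: int = 3
    iterations: int = 11000
    burn_in: int = 1000
    thin: int = 10
    # elasticity / spatial
    perturb_fraction: float = 0.10
    center: tuple | None = None  # (lon, lat); default: centroid of sites

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(out: Path, *names):
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise StageDependencyError(
            f"missing upstream outputs {missing}; run the earlier stages first")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    study = syn.make_study(cfg.n_sites, cfg.n_years, seed=cfg.seed,
                           missing_fraction=cfg.missing_fraction)
    syn.write_study(study, out)

    # a representative subset of sampling events with individual lengths,
    # for the length-splitting stage (counts capped to keep runs desk-scale)
    rng = np.random.default_rng((cfg.seed, 1))
    panel = study["panel"]
    temps = study["temperature_summaries"].set_index(["site_id", "year"])
    obs = [(i, t) for i in range(panel.n_sites) for t in range(panel.n_years)
           if panel.mask[i, t]]
    rng.shuffle(obs)
    rows = []
    for e, (i, t) in enumerate(obs[: cfg.n_events]):
        n0 = int(min(cfg.max_event_count, round(np.expm1(panel.X0[i, t]) ** 0.5 * 8)))
        n1 = int(min(cfg.max_event_count, round(np.expm1(panel.X1[i, t]) ** 0.5 * 8)))
        site, year = panel.site_ids[i], panel.years[t]
        t_mean = temps.loc[(site, year), "t_mean"]
        dd = float(max(0.0, t_mean - lc.GROWTH_THRESHOLD_C) * 365)
        rows.append({"event_id": f"E{e:03d}", "site_id": site, "year": year,
                     "area_m2": panel.S[i, t], "n0": max(n0, 0), "n1": max(n1, 5),
                     "degree_days": dd})
    counts = pd.DataFrame(rows)
    individuals = syn.simulate_lengths(counts, seed=int(rng.integers(2**31)))
    events = individuals.merge(counts[["event_id", "site_id", "year", "area_m2",
                                       "degree_days"]], on="event_id")
    events["event_count"] = events.groupby("event_id")["length_mm"].transform("size")
    events.to_csv(out / "events.csv", index=False)
    return ["sites.csv", "temperature_summaries.csv", "covariates.csv",
            "abundance.csv", "truth.json", "events.csv", "manifest.json"]


def stage_split_sizes(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "events.csv")
    events = pd.read_csv(out / "events.csv")

    # calibration: the most clearly bimodal events (largest balanced counts)
    sizes = events.groupby("event_id")["label"].agg(
        n0=lambda s: (s == 0).sum(), n1=lambda s: (s == 1).sum())
    calib_ids = sizes.assign(score=sizes.min(axis=1)).nlargest(20, "score").index

    fits = {}
    labeled = []
    for eid in calib_ids:
        sub = events[events["event_id"] == eid]
        try:
            fit = lc.fit_length_mixture(sub["length_mm"].to_numpy(), seed=cfg.seed)
        except lc.InsufficientDataError:
            continue
        fits[eid] = {"weights": fit.weights.tolist(), "means": fit.means.tolist(),
                     "sds": fit.sds.tolist(), "boundary": fit.boundary,
                     "converged": fit.converged, "loglik": fit.loglik}
        sub = sub.copy()
        sub["label"] = (sub["length_mm"] > fit.boundary).astype(int)
        labeled.append(sub)
    labeled = pd.concat(labeled, ignore_index=True)

    clf = lc.train_status_classifier(labeled, seed=cfg.seed)
    kappa = lc.cross_validate_kappa(labeled, n_splits=cfg.kappa_splits,
                                    seed=cfg.seed)

    classified = events.copy()
    classified["label"] = clf.predict(classified[lc.FEATURES].to_numpy())
    classified.to_csv(out / "classified_individuals.csv", index=False)
    abund = lc.aggregate_counts(classified)
    abund = abund.merge(events[["event_id", "site_id", "year", "area_m2"]]
                        .drop_duplicates(), on="event_id")
    abund.to_csv(out / "abundance_events.csv", index=False)
    (out / "mixture_fits.json").write_text(json.dumps(fits, indent=1))
    (out / "kappa.json").write_text(json.dumps(
        {"mean_kappa": float(np.nanmean(kappa["kappa"])),
         "n_splits": len(kappa),
         "n_missing": int(kappa["kappa"].isna().sum())}, indent=1))
    return ["classified_individuals.csv", "abundance_events.csv",
            "mixture_fits.json", "kappa.json"]


def stage_covariates(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "temperature_summaries.csv")
    summary = pd.read_csv(out / "temperature_summaries.csv")
    U = cov.build_U(summary)
    U.to_frame().to_csv(out / "covariates.csv", index=False)
    (out / "standardization.json").write_text(json.dumps(U.standardization, indent=1))
    return ["covariates.csv", "standardization.json"]


def stage_filter(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "abundance.csv")
    df = pd.read_csv(out / "abundance.csv")
    status = df.assign(
        observed=df["observed"].astype(bool),
        nonnull=(df[["x0", "x1"]].fillna(0).sum(axis=1) > 0),
    )[["site_id", "year", "observed", "nonnull"]]
    report = hm.filter_time_series(status, min_years=cfg.min_years,
                                   min_nonnull=cfg.min_nonnull,
                                   max_gap=cfg.max_gap)
    report.to_csv(out / "filter_report.csv", index=False)
    return ["filter_report.csv"]


def stage_fit(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "abundance.csv", "covariates.csv", "filter_report.csv")
    panel = fio.read_abundance_csv(out / "abundance.csv")
    U = fio.read_covariates_csv(out / "covariates.csv")
    report = pd.read_csv(out / "filter_report.csv")
    keep = list(report.loc[report["retained"], "site_id"])
    panel = fio.subset_panel(panel, keep)
    U = fio.subset_covariates(U, keep)

    model = hm.build_model(panel, U)
    draws = hm.fit(model, chains=cfg.chains, iterations=cfg.iterations,
                   burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed)
    summary = draws.summary()
    summary.to_csv(out / "posterior_summary.csv", index=False)
    medians = draws.site_medians()
    med = pd.DataFrame(medians.values, columns=list(hm.FAMILIES))
    med.insert(0, "site_id", keep)
    med.to_csv(out / "site_medians.csv", index=False)
    ppc = hm.posterior_predictive_check(draws, model, seed=cfg.seed)
    (out / "ppc.json").write_text(json.dumps(ppc, indent=1))
    return ["posterior_summary.csv", "site_medians.csv", "ppc.json"]


def stage_elasticity(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "site_medians.csv", "abundance.csv", "covariates.csv",
             "filter_report.csv")
    med = pd.read_csv(out / "site_medians.csv")
    keep = list(med["site_id"])
    panel = fio.subset_panel(fio.read_abundance_csv(out / "abundance.csv"), keep)
    U = fio.subset_covariates(fio.read_covariates_csv(out / "covariates.csv"), keep)
    medians = hm.SiteParams(values=med[list(hm.FAMILIES)].to_numpy(),
                            site_ids=keep)
    result = ela.elasticity_analysis(medians, panel, U,
                                     perturb_fraction=cfg.perturb_fraction)
    long = []
    for omega, arr in result.e.items():
        for i, site in enumerate(panel.site_ids):
            for t, year in enumerate(panel.years):
                long.append({"omega": omega, "site_id": site, "year": year,
                             "value": arr[i, t]})
    pd.DataFrame(long).to_csv(out / "elasticity.csv", index=False)
    result.site_mean.to_csv(out / "elasticity_site_means.csv", index=False)
    (out / "elasticity_species.json").write_text(json.dumps(
        {"species_mean": result.species_mean,
         "perturb_fraction": result.perturb_fraction,
         "n_excluded": len(result.excluded_points)}, indent=1))
    return ["elasticity.csv", "elasticity_site_means.csv",
            "elasticity_species.json"]


def stage_spatial(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    _require(out, "elasticity_site_means.csv", "sites.csv")
    site_means = pd.read_csv(out / "elasticity_site_means.csv")
    sites = pd.read_csv(out / "sites.csv")
    center = cfg.center or (float(sites["longitude"].mean()),
                            float(sites["latitude"].mean()))
    sites["distance_to_center"] = cov.distance_to_center(sites, center)
    result = sp.run_selection(site_means, sites)
    result.table.to_csv(out / "model_selection.csv", index=False)
    (out / "model_selection_coefficients.json").write_text(json.dumps(
        {"verdict": result.table.attrs.get("verdict"),
         "coefficients": result.coefficients}, indent=1))
    return ["model_selection.csv", "model_selection_coefficients.json"]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "split_sizes": stage_split_sizes,
    "covariates": stage_covariates, "filter": stage_filter, "fit": stage_fit,
    "elasticity": stage_elasticity, "spatial": stage_spatial,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "stages": []}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](cfg)
        manifest["stages"].append({
            "stage": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {name: _sha256(out / name) for name in outputs
                        if (out / name).exists()},
        })
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
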