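"""Temperature and spatial covariates.

The population model uses an array ``U`` of z-scored annual water-temperature
summaries (mean and intra-annual variability between consecutive sampling
occasions, plus their squares) as regressors, and three site-level spatial
covariates (elevation, latitude, great-circle distance to the geographic range
center) for the downstream gradient analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: order of the j-index in U: linear mean, squared mean, linear SD, squared SD
U_NAMES = ("tmean", "tmean2", "tvar", "tvar2")


@dataclass
class CovariatePanel:
    """z-scored temperature covariates indexed (j, site, year).

    ``values[0]``/``values[2]`` hold the z-scored annual mean and intra-annual
    SD of water temperature; ``values[1]``/``values[3]`` are their elementwise
    squares (quadratic terms are built *after* standardization).
    ``standardization`` stores the pooled mean/SD used for each linear
    variable so the transform is invertible.
    """

    values: np.ndarray  # (4, n_sites, n_years)
    site_ids: list
    years: list
    standardization: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def n_years(self) -> int:
        return self.values.shape[2]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.site_ids, self.years], names=["site_id", "year"]
        )
        data = {name: self.values[j].ravel() for j, name in enumerate(U_NAMES)}
        return pd.DataFrame(data, index=idx).reset_index()


@dataclass
class SiteInfo:
    """Static description of a sampling site."""

    site_id: object
    longitude: float
    latitude: float
    elevation: float
    distance_to_center: float | None = None


def summarize_temperature(
    daily: pd.DataFrame,
    sampling_dates: pd.DataFrame,
    min_days: int = 30,
    first_year_lookback_days: int = 365,
) -> pd.DataFrame:
    """Annual mean and variability of water temperature per site-year.

    For each sampling occasion the summary window runs from the previous
    sampling occasion (exclusive) to the current one (inclusive); the first
    occasion of a site looks back ``first_year_lookback_days`` days.  Windows
    with fewer than ``min_days`` daily values yield missing covariates.

    Parameters
    ----------
    daily:
        Columns ``site_id``, ``date`` (datetime-like), ``temp_c``.
    sampling_dates:
        Columns ``site_id``, ``date`` (one row per sampling occasion).

    Returns
    -------
    DataFrame with columns ``site_id, year, t_mean, t_var, n_days`` where
    ``t_var`` is the SD of daily values in the window (NaN when below
    ``min_days``).
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    sampling_dates = sampling_dates.copy()
    sampling_dates["date"] = pd.to_datetime(sampling_dates["date"])

    rows = []
    for site_id, grp in sampling_dates.groupby("site_id", sort=False):
        temps = daily.loc[daily["site_id"] == site_id].sort_values("date")
        dates = sorted(grp["date"])
        prev = None
        for d in dates:
            start = prev if prev is not None else d - pd.Timedelta(days=first_year_lookback_days)
            window = temps.loc[(temps["date"] > start) & (temps["date"] <= d), "temp_c"]
            n = int(window.notna().sum())
            if n >= min_days:
                t_mean = float(window.mean())
                t_var = float(window.std(ddof=1))
            else:
                t_mean = np.nan
                t_var = np.nan
            rows.append(
                {"site_id": site_id, "year": int(d.year), "t_mean": t_mean,
                 "t_var": t_var, "n_days": n}
            )
            prev = d
    return pd.DataFrame(rows)


def build_U(summary: pd.DataFrame, site_ids=None, years=None) -> CovariatePanel:
    """Assemble the covariate array from per-site-year temperature summaries.

    Each linear variable is z-scored over all site-years pooled (sample SD);
    squared entries are squares of the z-scored values.  Missing site-years
    are filled with 0 (the pooled mean) so the model's design stays complete;
    zero-variance variables are rejected.
    """
    if site_ids is None:
        site_ids = sorted(summary["site_id"].unique())
    if years is None:
        years = sorted(summary["year"].unique())
    n_sites, n_years = len(site_ids), len(years)

    values = np.zeros((4, n_sites, n_years))
    standardization = {}
    site_pos = {s: i for i, s in enumerate(site_ids)}
    year_pos = {y: t for t, y in enumerate(years)}

    for lin_j, sq_j, col in ((0, 1, "t_mean"), (2, 3, "t_var")):
        vals = summary[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if np.unique(finite).size < 2:
            raise ValueError(f"covariate {col!r} has no variance; cannot z-score")
        mean = float(np.mean(finite))
        sd = float(np.std(finite, ddof=1))
        standardization[col] = {"mean": mean, "sd": sd}
        grid = np.zeros((n_sites, n_years))
        for site, year, v in zip(summary["site_id"], summary["year"], vals):
            if np.isfinite(v) and site in site_pos and year in year_pos:
                grid[site_pos[site], year_pos[year]] = (v - mean) / sd
        values[lin_j] = grid
        values[sq_j] = grid**2

    return CovariatePanel(values=values, site_ids=list(site_ids), years=list(years),
                          standardization=standardization)


def _check_coords(lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range: |lat| <= 90, |lon| <= 180 required")
    return lon, lat


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between points in decimal degrees, in km."""
    lon1, lat1 = _check_coords(lon1, lat1)
    lon2, lat2 = _check_coords(lon2, lat2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_center(sites: pd.DataFrame, center: tuple[float, float]) -> np.ndarray:
    """Haversine distance (km) from each site to the supplied range center.

    ``center`` is (longitude, latitude); the range center is an input to the
    pipeline, computed upstream from range maps.
    """
    if center is None or len(center) != 2:
        raise ValueError("center must be a (longitude, latitude) pair")
    lon_c, lat_c = float(center[0]), float(center[1])
    return haversine_km(sites["longitude"].to_numpy(), sites["latitude"].to_numpy(),
                        lon_c, lat_c)
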