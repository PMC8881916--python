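"""File-format bridging: CSV panels and R-serialized model inputs."""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariatePanel, U_NAMES
from .errors import SchemaMismatchError
from .hier_model import AbundancePanel


def read_abundance_csv(path) -> AbundancePanel:
    """Load a long-format abundance CSV (site_id, year, x0, x1, area_m2, observed)."""
    df = pd.read_csv(path)
    site_ids = sorted(df["site_id"].unique())
    years = sorted(df["year"].unique())
    n, T = len(site_ids), len(years)
    X0 = np.full((n, T), np.nan)
    X1 = np.full((n, T), np.nan)
    S = np.full((n, T), np.nan)
    mask = np.zeros((n, T), dtype=bool)
    spos = {s: i for i, s in enumerate(site_ids)}
    ypos = {y: t for t, y in enumerate(years)}
    for row in df.itertuples(index=False):
        i, t = spos[row.site_id], ypos[row.year]
        X0[i, t], X1[i, t], S[i, t] = row.x0, row.x1, row.area_m2
        mask[i, t] = bool(row.observed) and np.isfinite(row.x0) and np.isfinite(row.x1)
    return AbundancePanel(X0=X0, X1=X1, S=S, mask=mask,
                          site_ids=site_ids, years=years)


def read_covariates_csv(path) -> CovariatePanel:
    """Load a long-format covariate CSV (site_id, year, tmean, tmean2, tvar, tvar2)."""
    df = pd.read_csv(path)
    site_ids = sorted(df["site_id"].unique())
    years = sorted(df["year"].unique())
    values = np.zeros((4, len(site_ids), len(years)))
    spos = {s: i for i, s in enumerate(site_ids)}
    ypos = {y: t for t, y in enumerate(years)}
    for row in df.itertuples(index=False):
        i, t = spos[row.site_id], ypos[row.year]
        for j, name in enumerate(U_NAMES):
            values[j, i, t] = getattr(row, name)
    return CovariatePanel(values=values, site_ids=site_ids, years=years)


def subset_panel(panel: AbundancePanel, keep_sites) -> AbundancePanel:
    idx = [panel.site_ids.index(s) for s in keep_sites]
    return AbundancePanel(X0=panel.X0[idx], X1=panel.X1[idx], S=panel.S[idx],
                          mask=panel.mask[idx], site_ids=list(keep_sites),
                          years=panel.years)


def subset_covariates(U: CovariatePanel, keep_sites) -> CovariatePanel:
    idx = [U.site_ids.index(s) for s in keep_sites]
    return CovariatePanel(values=U.values[:, idx, :], site_ids=list(keep_sites),
                          years=U.years, standardization=U.standardization)


_R_DUMP = r"""
args <- commandArgs(trailingOnly = TRUE)
loaded <- new.env()
nm <- load(args[1], envir = loaded)
out <- list()
for (v in nm) {
  obj <- get(v, envir = loaded)
  if (is.numeric(obj)) {
    out[[v]] <- list(dim = if (is.null(dim(obj))) length(obj) else dim(obj),
                     data = as.vector(obj))
  } else if (is.data.frame(obj)) {
    out[[v]] <- list(dim = dim(obj), columns = names(obj),
                     data = lapply(obj, function(x) as.vector(x)))
  } else {
    out[[v]] <- list(class = class(obj))
  }
}
writeLines(jsonlite::toJSON(out, digits = 15, null = "null"), args[2])
"""


def load_rdata_arrays(path) -> dict:
    """Read every numeric object from an RData/RDS file via an Rscript bridge.

    Returns a mapping name -> numpy array (reshaped to the stored dims,
    Fortran order as R stores them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tempfile.TemporaryDirectory() as tmp:
        script = Path(tmp) / "dump.R"
        out_json = Path(tmp) / "dump.json"
        script.write_text(_R_DUMP)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(path), str(out_json)],
            capture_output=True, text=True)
        if proc.returncode != 0 or not out_json.exists():
            raise SchemaMismatchError(
                f"could not parse {path} as R serialization: {proc.stderr.strip()}")
        raw = json.loads(out_json.read_text())
    arrays = {}
    for name, spec in raw.items():
        if "data" not in spec or isinstance(spec.get("data"), dict):
            continue
        dim = spec["dim"] if isinstance(spec["dim"], list) else [spec["dim"]]
        data = np.array([np.nan if v is None or v == "NA" else v
                         for v in spec["data"]], dtype=float)
        arrays[name] = data.reshape(dim, order="F") if len(dim) > 1 else data
    return arrays


def import_supplementary(path):
    """Map a deposited model-input RData file onto panel objects.

    Variable names inside such files are not standardized, so the importer
    discovers them: it looks for two (site, year) log-abundance matrices, a
    matching sampling-area matrix and a covariate array with four entries in
    one dimension.  Raises :class:`SchemaMismatchError` listing everything it
    found when the mapping is ambiguous or incomplete.

    Returns ``(panel, U, names)`` where ``names`` records which file variable
    fed which slot.
    """
    arrays = load_rdata_arrays(path)
    mats2 = {k: v for k, v in arrays.items() if v.ndim == 2}
    shapes = {}
    for k, v in mats2.items():
        shapes.setdefault(v.shape, []).append(k)
    panel_shape = None
    for shape, names in sorted(shapes.items(), key=lambda kv: -len(kv[1])):
        if len(names) >= 3:
            panel_shape = shape
            break
    u_name = next((k for k, v in arrays.items()
                   if v.ndim == 3 and 4 in v.shape), None)
    if panel_shape is None or u_name is None:
        raise SchemaMismatchError(
            "could not identify abundance/area matrices and covariate array",
            found=[f"{k}:{arrays[k].shape}" for k in sorted(arrays)])

    cands = shapes[panel_shape]

    def _pick(pred, pool):
        hits = [k for k in pool if pred(k.lower())]
        return hits[0] if hits else None

    s_name = _pick(lambda k: any(w in k for w in ("area", "surf", "offset", "samp")),
                   cands)
    x0_name = _pick(lambda k: k != s_name and any(w in k for w in ("0", "juv", "yoy", "rec")),
                    cands)
    x1_name = next((k for k in cands if k not in (s_name, x0_name)), None)
    if None in (s_name, x0_name, x1_name):
        raise SchemaMismatchError(
            "ambiguous variable mapping", found=[f"{k}:{mats2[k].shape}" for k in cands])

    X0, X1, S = arrays[x0_name], arrays[x1_name], arrays[s_name]
    u = arrays[u_name]
    j_axis = list(u.shape).index(4)
    u = np.moveaxis(u, j_axis, 0)
    if u.shape[1:] != panel_shape:
        if u.shape[:0:-1] == panel_shape:
            u = np.transpose(u, (0, 2, 1))
        else:
            raise SchemaMismatchError(
                f"covariate array {u_name} shape {arrays[u_name].shape} does not "
                f"match panel shape {panel_shape}")
    mask = np.isfinite(X0) & np.isfinite(X1)
    site_ids = [f"site{i}" for i in range(panel_shape[0])]
    years = list(range(panel_shape[1]))
    panel = AbundancePanel(X0=X0, X1=X1, S=S, mask=mask,
                           site_ids=site_ids, years=years)
    U = CovariatePanel(values=u, site_ids=site_ids, years=years)
    names = {"X0": x0_name, "X1": x1_name, "S": s_name, "U": u_name}
    return panel, U, names
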