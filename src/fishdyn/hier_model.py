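"""Hierarchical Bayesian two-size-class population dynamics model.

Log-abundances of young-of-the-year (0+) and older (>0+) fish at site *i*,
year *t* are modelled as normal around expected values driven by density
dependence, a 0+ -> >0+ transition, temperature covariates and sampling-area
offsets::

    X0[i,t] ~ Normal(lam0[i,t], sd0)
    X1[i,t] ~ Normal(lam1[i,t], sd1)

    lam0[i,t] = a0[i] + b0[i]*X1[i,t]/log S[i,t] + sum_j g0[i,j]*U[j,i,t]
                + log S[i,t]
    lam1[i,t] = a1[i] + X1[i,t-1] + b1[i]*X1[i,t-1]/log S[i,t-1]
                + d1[i]*X0[i,t-1]/log S[i,t-1] + sum_j g1[i,j]*U[j,i,t]
                + log(S[i,t]/S[i,t-1])

The >0+ equation is a modified stochastic Gompertz model: ``a1`` is the
productivity rate, ``b1`` the strength of density dependence, ``d1`` the
apparent survival (transition) rate, and ``b0`` the apparent recruitment
rate.  Site coefficients are exchangeable draws from normal hyper
distributions (mean = large-scale value, SD = spatial variability); hyper
means get Normal(0, 10) priors, all SD scales get half-Cauchy priors.

Inference is by a blocked Gibbs sampler: site-coefficient vectors, hyper
means and latent (missing-year) log-abundances all have conjugate normal
full conditionals because every equation is linear in them; the half-Cauchy
SD scales are updated by univariate slice sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: coefficient families, in storage order (columns of the per-site matrix)
FAMILIES = (
    "alpha0", "beta0", "g0_tmean", "g0_tmean2", "g0_tvar", "g0_tvar2",
    "alpha1", "beta1", "delta1", "g1_tmean", "g1_tmean2", "g1_tvar", "g1_tvar2",
)
IDX0 = slice(0, 6)   # columns entering the 0+ equation
IDX1 = slice(6, 13)  # columns entering the >0+ equation
N_FAM = len(FAMILIES)


@dataclass
class AbundancePanel:
    """Per-site annual log-abundances of the two size classes.

    ``X0``/``X1`` are (n_sites, n_years) log-abundance arrays, ``S`` the
    matching sampled areas (m^2, must exceed 1 so log S > 0) and ``mask`` a
    boolean array flagging observed site-years (False = missing).
    """

    X0: np.ndarray
    X1: np.ndarray
    S: np.ndarray
    mask: np.ndarray
    site_ids: list
    years: list

    def __post_init__(self):
        self.X0 = np.asarray(self.X0, dtype=float)
        self.X1 = np.asarray(self.X1, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.X0.shape == self.X1.shape == self.S.shape == self.mask.shape):
            raise ValueError("X0, X1, S and mask must share one (site, year) shape")
        if np.any(self.S[self.mask] <= 1.0):
            raise ValueError("sampled areas must exceed 1 m^2 (log-area offset)")

    @property
    def n_sites(self) -> int:
        return self.X0.shape[0]

    @property
    def n_years(self) -> int:
        return self.X0.shape[1]

    def log_area(self) -> np.ndarray:
        return np.log(self.S)


@dataclass
class SiteParams:
    """Per-site coefficient matrix, columns ordered as :data:`FAMILIES`."""

    values: np.ndarray  # (n_sites, 13)
    site_ids: list = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_FAM:
            raise ValueError(f"expected {N_FAM} coefficient families per site")

    def col(self, family: str) -> np.ndarray:
        return self.values[:, FAMILIES.index(family)]


@dataclass
class HyperParams:
    mu: np.ndarray      # (13,) family means
    sigma: np.ndarray   # (13,) family SDs
    process_sd0: float
    process_sd1: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (N_FAM,) or self.sigma.shape != (N_FAM,):
            raise ValueError(f"mu and sigma must have length {N_FAM}")
        if np.any(self.sigma < 0) or self.process_sd0 <= 0 or self.process_sd1 <= 0:
            raise ValueError("SD scales must be non-negative (process SDs positive)")


@dataclass
class PosteriorDraws:
    """MCMC output: arrays indexed (chain, draw, ...)."""

    mu: np.ndarray         # (chains, draws, 13)
    sigma: np.ndarray      # (chains, draws, 13)
    process_sd: np.ndarray  # (chains, draws, 2)
    theta: np.ndarray      # (chains, draws, n_sites, 13)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    def scalar_draws(self) -> dict:
        """Named (chain, draw) arrays for every hyper-level scalar."""
        out = {}
        for k, fam in enumerate(FAMILIES):
            out[f"mu_{fam}"] = self.mu[:, :, k]
            out[f"sigma_{fam}"] = self.sigma[:, :, k]
        out["process_sd0"] = self.process_sd[:, :, 0]
        out["process_sd1"] = self.process_sd[:, :, 1]
        return out

    def site_medians(self) -> SiteParams:
        """Posterior medians of the site coefficients, pooled over chains."""
        flat = self.theta.reshape(-1, *self.theta.shape[2:])
        return SiteParams(values=np.median(flat, axis=0))

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        rhat = gelman_rubin(self) if self.n_chains >= 2 else None
        for name, arr in self.scalar_draws().items():
            pooled = arr.ravel()
            lo, hi = hpd_interval(pooled, prob)
            rows.append({"parameter": name, "median": float(np.median(pooled)),
                         "hpd_low": lo, "hpd_high": hi,
                         "rhat": float(rhat[name]) if rhat is not None else np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eligibility filters
# ---------------------------------------------------------------------------

def _longest_false_run(flags: np.ndarray) -> int:
    run = best = 0
    for f in flags:
        run = 0 if f else run + 1
        best = max(best, run)
    return best


def filter_time_series(status: pd.DataFrame, min_years: int = 15,
                       min_nonnull: float = 0.5, max_gap: int = 3) -> pd.DataFrame:
    """Apply the time-series eligibility filters site by site.

    ``status`` has one row per site-year with columns ``site_id``, ``year``,
    ``observed`` (a sampling event happened) and ``nonnull`` (at least one
    capture, both size classes confounded).  A site is retained iff it has at
    least ``min_years`` observed years, at least ``min_nonnull`` non-null
    fraction among observed years, and no gap of more than ``max_gap``
    consecutive missing years within its observed span.
    """
    rows = []
    for site_id, grp in status.groupby("site_id", sort=False):
        grp = grp.sort_values("year")
        obs = grp["observed"].to_numpy(dtype=bool)
        span = grp.loc[obs, "year"]
        if span.empty:
            rows.append({"site_id": site_id, "retained": False, "n_observed": 0,
                         "nonnull_fraction": np.nan, "longest_gap": np.nan,
                         "reason": "no observed years"})
            continue
        lo, hi = int(span.min()), int(span.max())
        in_span = grp[(grp["year"] >= lo) & (grp["year"] <= hi)]
        obs_span = in_span["observed"].to_numpy(dtype=bool)
        n_obs = int(obs_span.sum())
        nonnull = float(in_span.loc[obs_span, "nonnull"].mean())
        gap = _longest_false_run(obs_span)
        reasons = []
        if n_obs < min_years:
            reasons.append(f"only {n_obs} observed years (< {min_years})")
        if nonnull < min_nonnull:
            reasons.append(f"non-null fraction {nonnull:.2f} (< {min_nonnull})")
        if gap > max_gap:
            reasons.append(f"{gap} consecutive missing years (> {max_gap})")
        rows.append({"site_id": site_id, "retained": not reasons, "n_observed": n_obs,
                     "nonnull_fraction": nonnull, "longest_gap": gap,
                     "reason": "; ".join(reasons)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Joint density of the two-size-class model on a given panel."""

    panel: AbundancePanel
    U: "object"  # CovariatePanel
    mu_prior_sd: float = 10.0
    cauchy_scale: float = 2.5

    def __post_init__(self):
        if self.U.values.shape[1:] != self.panel.X0.shape:
            raise ValueError("covariate panel and abundance panel are misaligned")

    def expected_log_abundance(self, params: SiteParams,
                               X0: np.ndarray = None, X1: np.ndarray = None):
        """(lam0, lam1) arrays; lam1[:, 0] is NaN (no predecessor year)."""
        X0 = self.panel.X0 if X0 is None else X0
        X1 = self.panel.X1 if X1 is None else X1
        L = self.panel.log_area()
        U = self.U.values
        th = params.values
        a0, b0 = th[:, 0:1], th[:, 1:2]
        g0 = th[:, 2:6]
        a1, b1, d1 = th[:, 6:7], th[:, 7:8], th[:, 8:9]
        g1 = th[:, 9:13]

        lam0 = a0 + b0 * X1 / L + np.einsum("ij,jit->it", g0, U) + L
        lam1 = np.full_like(lam0, np.nan)
        lam1[:, 1:] = (a1 + X1[:, :-1] + b1 * X1[:, :-1] / L[:, :-1]
                       + d1 * X0[:, :-1] / L[:, :-1]
                       + np.einsum("ij,jit->it", g1, U[:, :, 1:])
                       + L[:, 1:] - L[:, :-1])
        return lam0, lam1

    def log_likelihood(self, params: SiteParams, process_sd0: float,
                       process_sd1: float) -> float:
        """Observation-layer log density over observed site-years only."""
        lam0, lam1 = self.expected_log_abundance(params)
        m = self.panel.mask
        m1 = m.copy()
        m1[:, 0] = False
        m1[:, 1:] &= m[:, :-1]  # >0+ needs the predecessor year too
        r0 = self.panel.X0[m] - lam0[m]
        r1 = self.panel.X1[m1] - lam1[m1]

        def _norm(r, sd):
            return float(-0.5 * np.sum((r / sd) ** 2)
                         - r.size * (math.log(sd) + 0.5 * math.log(2 * math.pi)))

        return _norm(r0, process_sd0) + _norm(r1, process_sd1)


def build_model(panel: AbundancePanel, U, mu_prior_sd: float = 10.0,
                cauchy_scale: float = 2.5) -> ModelSpec:
    """Assemble the joint model (validates panel/covariate alignment)."""
    return ModelSpec(panel=panel, U=U, mu_prior_sd=mu_prior_sd,
                     cauchy_scale=cauchy_scale)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _slice_sample(logp, x0: float, rng, w: float = 1.0, max_steps: int = 100) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    y = logp(x0) + math.log(rng.random())
    u = rng.random()
    lo, hi = x0 - u * w, x0 + (1.0 - u) * w
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(max_steps):
        x = lo + rng.random() * (hi - lo)
        if logp(x) > y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def _sd_logpost_log(u: float, n: int, ss: float, scale: float) -> float:
    """log p(log s | .) for s with half-Cauchy(scale) prior and n normal terms."""
    s = math.exp(u)
    return (-n * u - ss / (2.0 * s * s)
            - math.log1p((s / scale) ** 2) + u)  # + u: Jacobian of s -> log s


def _interpolate_missing(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = x.copy()
    for i in range(x.shape[0]):
        obs = np.flatnonzero(mask[i])
        if obs.size == 0:
            out[i] = 0.0
            continue
        miss = np.flatnonzero(~mask[i])
        if miss.size:
            out[i, miss] = np.interp(miss, obs, x[i, obs])
    return out


def _design(X0, X1, L, U):
    """(D0, y0, D1, y1) regression views of the two dynamic equations."""
    n, T = X0.shape
    D0 = np.empty((n, T, 6))
    D0[:, :, 0] = 1.0
    D0[:, :, 1] = X1 / L
    D0[:, :, 2:6] = np.moveaxis(U, 0, 2)
    y0 = X0 - L

    D1 = np.empty((n, T - 1, 7))
    D1[:, :, 0] = 1.0
    D1[:, :, 1] = X1[:, :-1] / L[:, :-1]
    D1[:, :, 2] = X0[:, :-1] / L[:, :-1]
    D1[:, :, 3:7] = np.moveaxis(U[:, :, 1:], 0, 2)
    y1 = X1[:, 1:] - X1[:, :-1] - (L[:, 1:] - L[:, :-1])
    return D0, y0, D1, y1


def _sample_coefs(D, y, sd, mu, sig, rng):
    """Batched conjugate draw of per-site coefficient vectors."""
    p = D.shape[2]
    prec_prior = 1.0 / sig**2
    A = np.einsum("itp,itq->ipq", D, D) / sd**2
    A[:, np.arange(p), np.arange(p)] += prec_prior
    b = np.einsum("itp,it->ip", D, y) / sd**2 + mu * prec_prior
    chol = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b[..., None])[..., 0]
    z = rng.standard_normal(b.shape)
    noise = np.linalg.solve(np.swapaxes(chol, 1, 2), z[..., None])[..., 0]
    return mean + noise


def fit(model: ModelSpec, chains: int = 3, iterations: int = 11000,
        burn_in: int = 1000, thin: int = 10, seed: int = 0,
        init_jitter: float = 0.5) -> PosteriorDraws:
    """Blocked Gibbs sampling of the hierarchical model.

    ``iterations`` is the total chain length; the first ``burn_in`` draws are
    discarded and the remainder kept every ``thin`` iterations.  Missing
    site-years are latent nodes with conjugate normal updates.  Chains start
    from jittered per-site ridge estimates so they begin in different regions
    of parameter space.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    panel, Uarr = model.panel, model.U.values
    n, T = panel.n_sites, panel.n_years
    if T < 2:
        raise ValueError("need at least two years")
    L = panel.log_area()
    # areas at missing years may be unrecorded; carry forward a site-typical area
    if not np.all(np.isfinite(L)):
        fill = np.nanmean(np.where(np.isfinite(L), L, np.nan), axis=1, keepdims=True)
        L = np.where(np.isfinite(L), L, fill)
    mask = panel.mask
    missing = [(i, t) for i in range(n) for t in range(T) if not mask[i, t]]
    n_keep = (iterations - burn_in) // thin

    keep_mu = np.empty((chains, n_keep, N_FAM))
    keep_sig = np.empty((chains, n_keep, N_FAM))
    keep_psd = np.empty((chains, n_keep, 2))
    keep_th = np.empty((chains, n_keep, n, N_FAM))

    X0_base = _interpolate_missing(panel.X0, mask)
    X1_base = _interpolate_missing(panel.X1, mask)
    anchor = np.array([X1_base[i][mask[i]].mean() if mask[i].any() else 0.0
                       for i in range(n)])

    for c in range(chains):
        rng = np.random.default_rng((seed, c))
        X0, X1 = X0_base.copy(), X1_base.copy()
        D0, y0, D1, y1 = _design(X0, X1, L, Uarr)

        # ridge start + overdispersed chain-specific jitter
        theta = np.empty((n, N_FAM))
        for D, y, sl in ((D0, y0, IDX0), (D1, y1, IDX1)):
            p = D.shape[2]
            A = np.einsum("itp,itq->ipq", D, D)
            A[:, np.arange(p), np.arange(p)] += 1e-2
            rhs = np.einsum("itp,it->ip", D, y)
            theta[:, sl] = np.linalg.solve(A, rhs[..., None])[..., 0]
        theta += rng.normal(0.0, init_jitter, size=theta.shape)
        mu = theta.mean(axis=0) + rng.normal(0.0, init_jitter, size=N_FAM)
        sig = np.maximum(theta.std(axis=0), 0.1) * np.exp(rng.normal(0, 0.3, N_FAM))
        s0 = float(np.std(y0 - np.einsum("itp,ip->it", D0, theta[:, IDX0])) + 1e-3)
        s1 = float(np.std(y1 - np.einsum("itp,ip->it", D1, theta[:, IDX1])) + 1e-3)
        s0 *= math.exp(rng.normal(0, 0.3))
        s1 *= math.exp(rng.normal(0, 0.3))

        k = 0
        for it in range(iterations):
            D0, y0, D1, y1 = _design(X0, X1, L, Uarr)
            theta[:, IDX0] = _sample_coefs(D0, y0, s0, mu[IDX0], sig[IDX0], rng)
            theta[:, IDX1] = _sample_coefs(D1, y1, s1, mu[IDX1], sig[IDX1], rng)

            # hyper means: Normal(0, mu_prior_sd) prior
            prec = n / sig**2 + 1.0 / model.mu_prior_sd**2
            mean = (theta.sum(axis=0) / sig**2) / prec
            mu = mean + rng.standard_normal(N_FAM) / np.sqrt(prec)

            # hyper SDs and process SDs: half-Cauchy, slice-sampled on log s
            dev2 = ((theta - mu) ** 2).sum(axis=0)
            for f in range(N_FAM):
                u = _slice_sample(
                    lambda v, ss=dev2[f]: _sd_logpost_log(v, n, ss, model.cauchy_scale),
                    math.log(sig[f]), rng)
                sig[f] = math.exp(u)
            r0 = y0 - np.einsum("itp,ip->it", D0, theta[:, IDX0])
            r1 = y1 - np.einsum("itp,ip->it", D1, theta[:, IDX1])
            s0 = math.exp(_slice_sample(
                lambda v: _sd_logpost_log(v, r0.size, float((r0**2).sum()),
                                          model.cauchy_scale), math.log(s0), rng))
            s1 = math.exp(_slice_sample(
                lambda v: _sd_logpost_log(v, r1.size, float((r1**2).sum()),
                                          model.cauchy_scale), math.log(s1), rng))

            if missing:
                _update_latent(X0, X1, L, Uarr, theta, s0, s1, missing, anchor, rng)

            if it >= burn_in and (it - burn_in) % thin == 0 and k < n_keep:
                keep_mu[c, k] = mu
                keep_sig[c, k] = sig
                keep_psd[c, k] = (s0, s1)
                keep_th[c, k] = theta
                k += 1

    return PosteriorDraws(mu=keep_mu, sigma=keep_sig, process_sd=keep_psd,
                          theta=keep_th,
                          meta={"chains": chains, "iterations": iterations,
                                "burn_in": burn_in, "thin": thin, "seed": seed,
                                "site_ids": list(panel.site_ids)})


def _update_latent(X0, X1, L, U, theta, s0, s1, missing, anchor, rng):
    """Conjugate normal updates of latent (missing) log-abundances."""
    T = X0.shape[1]
    v0, v1 = s0 * s0, s1 * s1
    for i, t in missing:
        a0, b0 = theta[i, 0], theta[i, 1]
        g0 = theta[i, 2:6]
        a1, b1, d1 = theta[i, 6], theta[i, 7], theta[i, 8]
        g1 = theta[i, 9:13]
        Lt = L[i, t]
        u_t = U[:, i, t]

        # --- X1[i, t] ---
        prec = 0.0
        num = 0.0
        if t >= 1:
            lam1 = (a1 + X1[i, t - 1] + b1 * X1[i, t - 1] / L[i, t - 1]
                    + d1 * X0[i, t - 1] / L[i, t - 1] + g1 @ u_t
                    + Lt - L[i, t - 1])
            prec += 1.0 / v1
            num += lam1 / v1
        else:
            prec += 1.0 / 100.0
            num += anchor[i] / 100.0
        c1 = b0 / Lt  # X1 feeds the same-year 0+ expectation
        r1 = X0[i, t] - (a0 + g0 @ u_t + Lt)
        prec += c1 * c1 / v0
        num += c1 * r1 / v0
        if t + 1 < T:  # X1 carries into next year's >0+ expectation
            c2 = 1.0 + b1 / Lt
            r2 = X1[i, t + 1] - (a1 + d1 * X0[i, t] / Lt + g1 @ U[:, i, t + 1]
                                 + L[i, t + 1] - Lt)
            prec += c2 * c2 / v1
            num += c2 * r2 / v1
        X1[i, t] = num / prec + rng.standard_normal() / math.sqrt(prec)

        # --- X0[i, t] ---
        lam0 = a0 + b0 * X1[i, t] / Lt + g0 @ u_t + Lt
        prec = 1.0 / v0
        num = lam0 / v0
        if t + 1 < T:  # X0 feeds next year's transition term
            c = d1 / Lt
            r = X1[i, t + 1] - (a1 + X1[i, t] + b1 * X1[i, t] / Lt
                                + g1 @ U[:, i, t + 1] + L[i, t + 1] - Lt)
            prec += c * c / v1
            num += c * r / v1
        X0[i, t] = num / prec + rng.standard_normal() / math.sqrt(prec)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Potential scale reduction factor per hyper-level scalar parameter."""
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    out = {}
    for name, arr in draws.scalar_draws().items():
        m, ndraw = arr.shape
        if ndraw < 2:
            raise ValueError("need at least 2 draws per chain")
        chain_means = arr.mean(axis=1)
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = np.var(chain_means, ddof=1)
        var_plus = (ndraw - 1) / ndraw * W + B_over_n
        out[name] = float(np.sqrt(var_plus / W)) if W > 0 else 1.0
    return pd.Series(out, name="rhat")


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the empirical distribution."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = max(1, math.ceil(prob * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:-k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_overlap(samples_a, samples_b, bins: int = 512) -> float:
    """Overlap coefficient of two posterior samples on a shared histogram grid."""
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    width = edges[1] - edges[0]
    return float(np.minimum(pa, pb).sum() * width)


def posterior_predictive_check(draws: PosteriorDraws, model: ModelSpec,
                               max_draws: int = 500, seed: int = 0) -> dict:
    """Chi-square discrepancy posterior predictive p-value per size class.

    For each retained draw, replicate data are simulated at the expected
    values implied by that draw's site coefficients; the p-value is the
    fraction of draws where the replicate discrepancy exceeds the observed
    one.  Values near 0.5 indicate good fit.
    """
    panel = model.panel
    n_total = draws.mu.shape[0] * draws.mu.shape[1]
    if n_total == 0:
        raise ValueError("no retained posterior draws")
    rng = np.random.default_rng(seed)
    theta_flat = draws.theta.reshape(-1, panel.n_sites, N_FAM)
    psd_flat = draws.process_sd.reshape(-1, 2)
    take = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)

    m = panel.mask
    m1 = m.copy()
    m1[:, 0] = False
    m1[:, 1:] &= m[:, :-1]

    exceed0 = exceed1 = 0
    for d in take:
        params = SiteParams(values=theta_flat[d])
        s0, s1 = psd_flat[d]
        lam0, lam1 = model.expected_log_abundance(params)
        r0 = (panel.X0[m] - lam0[m]) / s0
        r1 = (panel.X1[m1] - lam1[m1]) / s1
        rep0 = rng.standard_normal(r0.size)
        rep1 = rng.standard_normal(r1.size)
        exceed0 += (rep0 @ rep0) > (r0 @ r0)
        exceed1 += (rep1 @ rep1) > (r1 @ r1)
    return {"p_0plus": exceed0 / take.size, "p_oldplus": exceed1 / take.size,
            "n_draws": int(take.size)}
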