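"""Separation of young-of-the-year (0+) from older (>0+) fish.

Per sampling event, body lengths are modelled as a mixture of two normal
distributions (the 0+ and >0+ length-frequency components).  The class
boundary is the length at which the two weighted component densities cross.
Because the mixture is unreliable when the modes are poorly separated, a
probabilistic classifier is calibrated on a small set of clearly bimodal
events (features: individual length, event-level total count, and annual
degree-days above the growth threshold) and applied to the remaining events;
its skill is measured by repeated split-sample cross-validation with Cohen's
kappa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score
from sklearn.mixture import GaussianMixture

from .errors import DegenerateFitError, InsufficientDataError, NoBoundaryError

GROWTH_THRESHOLD_C = 12.0  # water temperature below which growth is assumed inhibited


@dataclass
class SamplingEvent:
    site_id: object
    date: object
    area: float
    lengths: np.ndarray

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.area <= 0:
            raise ValueError("sampled area must be positive")
        if self.lengths.size and np.any(self.lengths <= 0):
            raise ValueError("body lengths must be positive")


@dataclass
class MixtureFit:
    weights: np.ndarray   # (2,), sums to 1, component 0 = smaller mean
    means: np.ndarray     # (2,), mm
    sds: np.ndarray       # (2,), mm
    boundary: float       # mm, crossing point of the weighted densities
    converged: bool
    loglik: float


def fit_length_mixture(lengths, min_n: int = 10, max_iter: int = 500,
                       tol: float = 1e-6, seed: int = 0) -> MixtureFit:
    """EM fit of a two-component normal mixture to event body lengths.

    Components are returned ordered by mean (0+ first).  A fit where one
    component collapses onto a point (or the data are constant) raises
    :class:`DegenerateFitError`.
    """
    x = np.asarray(lengths, dtype=float).reshape(-1, 1)
    if x.shape[0] < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} lengths to fit a mixture, got {x.shape[0]}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all lengths identical; mixture is degenerate")

    gm = GaussianMixture(n_components=2, covariance_type="spherical",
                         max_iter=max_iter, tol=tol, reg_covar=1e-10,
                         init_params="kmeans", n_init=1, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)

    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    if np.any(sds < 1e-4) or np.any(weights < 1e-6):
        raise DegenerateFitError("a mixture component collapsed during EM")

    fit = MixtureFit(weights=weights, means=means, sds=sds, boundary=np.nan,
                     converged=bool(gm.converged_),
                     loglik=float(gm.score(x) * x.shape[0]))
    fit.boundary = crossing_boundary(fit)
    return fit


def crossing_boundary(fit: MixtureFit) -> float:
    """Length at which the two weighted normal densities cross.

    Solves ``w1*phi1(x) = w2*phi2(x)`` in closed form (quadratic in x after
    taking logs) and returns the root lying between the two means; falls back
    to bracketed root finding if the closed form yields none.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if math.isclose(m1, m2, rel_tol=0.0, abs_tol=1e-12):
        raise NoBoundaryError("component means are equal; no crossing point")

    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = (m2**2 / s2**2 - m1**2 / s1**2
         + 2.0 * (math.log(w1 / w2) + math.log(s2 / s1)))
    lo, hi = min(m1, m2), max(m1, m2)
    roots = []
    if abs(a) < 1e-14:  # equal SDs: linear equation
        if abs(b) > 1e-14:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = sorted(r for r in roots if lo < r < hi)
    if inside:
        return float(inside[0])

    def diff(x):
        return (math.log(w1) + norm.logpdf(x, m1, s1)
                - math.log(w2) - norm.logpdf(x, m2, s2))

    if diff(lo) * diff(hi) < 0:
        return float(brentq(diff, lo, hi))
    raise NoBoundaryError("no density crossing between the component means")


def degree_days(daily_temps, threshold: float = GROWTH_THRESHOLD_C) -> float:
    """Cumulative degree-days above the growth threshold: sum of max(0, T - threshold)."""
    t = np.asarray(daily_temps, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series is empty")
    return float(np.sum(np.clip(t - threshold, 0.0, None)))


FEATURES = ["length_mm", "event_count", "degree_days"]


def train_status_classifier(labeled: pd.DataFrame, n_estimators: int = 300,
                            seed: int = 0, classifier=None):
    """Train the individual 0+/>0+ status classifier.

    ``labeled`` needs one row per individual with columns ``length_mm``,
    ``event_count`` (total individuals in the event, a density-dependence
    proxy), ``degree_days`` and ``label`` (0 for 0+, 1 for >0+).  The default
    learner is a random forest; any sklearn-style probabilistic classifier can
    be passed instead.
    """
    labels = labeled["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both size classes")
    if "event_id" in labeled.columns and labeled["event_id"].nunique() < 2:
        raise ValueError("need at least 2 labeled events to train")
    clf = classifier or RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    clf.fit(labeled[FEATURES].to_numpy(), labels)
    return clf


def cross_validate_kappa(labeled: pd.DataFrame, n_splits: int = 100,
                         holdout_fraction: float = 0.3, seed: int = 0,
                         classifier_factory=None) -> pd.DataFrame:
    """Repeated split-sample cross-validation scored by Cohen's kappa.

    Each split holds out ``holdout_fraction`` of individuals at random, trains
    on the remainder and computes kappa on the holdout.  Splits whose training
    part is single-class are recorded as missing (NaN) with a warning.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(labeled)
    n_hold = max(1, int(round(holdout_fraction * n)))
    X = labeled[FEATURES].to_numpy()
    y = labeled["label"].to_numpy()

    kappas = np.full(n_splits, np.nan)
    for k in range(n_splits):
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        if np.unique(y[train]).size < 2:
            warnings.warn(f"split {k}: training part single-class; kappa undefined")
            continue
        if classifier_factory is not None:
            clf = classifier_factory()
        else:
            clf = RandomForestClassifier(n_estimators=100, n_jobs=1,
                                         random_state=int(rng.integers(2**31)))
        clf.fit(X[train], y[train])
        pred = clf.predict(X[hold])
        if np.unique(y[hold]).size < 2 and np.array_equal(pred, y[hold]):
            kappas[k] = 1.0  # perfect agreement on a one-class holdout
        else:
            kappas[k] = cohen_kappa_score(y[hold], pred)
    return pd.DataFrame({"split": np.arange(n_splits), "kappa": kappas})


def aggregate_counts(individuals: pd.DataFrame) -> pd.DataFrame:
    """Sum classified individuals per event into (n0, n1) size-class counts.

    ``individuals`` has one row per fish with ``event_id`` and ``label``
    (0 or 1); every individual must be classified.
    """
    if individuals["label"].isna().any():
        raise ValueError("all individuals must be classified before aggregation")
    grouped = individuals.groupby("event_id")["label"]
    out = pd.DataFrame({
        "n0": grouped.apply(lambda s: int((s == 0).sum())),
        "n1": grouped.apply(lambda s: int((s == 1).sum())),
    }).reset_index()
    return out
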