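"""Disparity through time and macroevolutionary model comparison.

Disparity is the within-bin sum of variance (SOV): the sum over ordination
axes of the sample variance of the lineages present in a time bin, i.e. the
trace of their covariance matrix — a disparity metric relatively robust to
sample size. Lineages per bin come from phylogenetic time-slicing at the bin
midpoint, so unsampled branches contribute reconstructed values. Bootstrap
resampling (default 1000 cycles) gives 95% percentile confidence intervals,
optionally with rarefaction to the minimum across-bin lineage count.

The resulting disparity series can be compared against five standard
paleontological time-series models — Brownian motion (BM), directional
Trend, Stasis, Ornstein-Uhlenbeck constraint (OU), and Early Burst (EB) —
fitted by maximum likelihood with per-bin sampling variance folded into the
likelihood, ranked by AICc and Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phylo import time_slice

__all__ = [
    "DisparityCurve",
    "SeriesModelFit",
    "sum_of_variance",
    "disparity_through_time",
    "fit_series_models",
    "SERIES_MODELS",
]

DEFAULT_BOOTSTRAP = 1000
SERIES_MODELS = ("BM", "Trend", "Stasis", "OU", "EB")


@dataclass
class DisparityCurve:
    bins: list  # (older Ma, younger Ma), oldest first
    point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_lineages: np.ndarray
    boot_var: np.ndarray = None  # bootstrap sampling variance per bin
    rarefied_to: int = None
    B: int = DEFAULT_BOOTSTRAP
    seed: int = None

    def to_frame(self):
        return pd.DataFrame(
            {
                "bin_older_ma": [b[0] for b in self.bins],
                "bin_younger_ma": [b[1] for b in self.bins],
                "sov": self.point,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_lineages": self.n_lineages,
            }
        )

    def usable(self):
        """Indices of bins with a defined SOV (>= 2 lineages)."""
        return np.flatnonzero(self.n_lineages >= 2)


@dataclass
class SeriesModelFit:
    model: str
    params: dict
    log_likelihood: float
    n_params: int
    n_obs: int
    aicc: float
    akaike_weight: float = None

    def summary_row(self):
        return {
            "model": self.model,
            "logL": self.log_likelihood,
            "AICc": self.aicc,
            "weight": self.akaike_weight,
            **{f"p_{k}": v for k, v in self.params.items()},
        }


# -- SOV ------------------------------------------------------------------------


def sum_of_variance(vectors):
    """Sum over axes of the sample (n-1) variance of the given vectors."""
    V = np.asarray(vectors, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if len(V) < 2:
        raise ValueError("SOV undefined for fewer than 2 vectors")
    return float(V.var(axis=0, ddof=1).sum())


# -- disparity curve --------------------------------------------------------------


def disparity_through_time(tree, node_values, bins, slice_model="proximity",
                           B=DEFAULT_BOOTSTRAP, rarefy=False, seed=None,
                           slice_at="midpoint"):
    """Sum-of-variance disparity per time bin with bootstrap 95% CIs.

    Parameters
    ----------
    tree : TimeTree
    node_values : dict
        Node id -> trait/PC vector for every node and tip.
    bins : list of (older Ma, younger Ma) pairs, oldest first.
    slice_model : {"proximity", "gradual"}
        How branch values are read at the slice age.
    B : int
        Bootstrap cycles (lineages resampled with replacement).
    rarefy : bool
        Subsample each bootstrap draw without replacement to the minimum
        across-bin lineage count.
    slice_at : {"midpoint", "boundary"}
        Slice each bin at its midpoint or at its older boundary.
    """
    bins = [tuple(map(float, b)) for b in bins]
    for older, younger in bins:
        if older <= younger:
            raise ValueError("bins must be (older, younger) with older > younger")
    rng = np.random.default_rng(seed)
    slices = []
    for older, younger in bins:
        age = 0.5 * (older + younger) if slice_at == "midpoint" else older
        sl = time_slice(tree, age, node_values, model=slice_model)
        slices.append(sl.matrix())
    counts = np.array([len(m) for m in slices])
    usable = counts >= 2
    r_min = int(counts[usable].min()) if rarefy and usable.any() else None

    point = np.full(len(bins), np.nan)
    lo = np.full(len(bins), np.nan)
    hi = np.full(len(bins), np.nan)
    bvar = np.full(len(bins), np.nan)
    for i, M in enumerate(slices):
        if counts[i] < 2:
            continue
        point[i] = sum_of_variance(M)
        stats = np.empty(B)
        n = len(M)
        for b in range(B):
            draw = M[rng.integers(0, n, size=n)]
            if r_min is not None and r_min < n:
                sub = rng.choice(n, size=r_min, replace=False)
                draw = draw[sub]
            if len(np.unique(draw, axis=0)) < 2:
                stats[b] = 0.0
            else:
                stats[b] = sum_of_variance(draw)
        lo[i], hi[i] = np.percentile(stats, [2.5, 97.5])
        bvar[i] = stats.var(ddof=1)
        if rarefy and r_min is not None and r_min < n:
            # point estimate from rarefaction-only draws (no bootstrap
            # resampling): subsampling without replacement keeps the n-1
            # variance unbiased, so rarefied SOV carries no sample-size bias
            rare = np.empty(B)
            for b in range(B):
                sub = rng.choice(n, size=r_min, replace=False)
                rare[b] = sum_of_variance(M[sub])
            point[i] = rare.mean()
    return DisparityCurve(
        bins=bins, point=point, ci_low=lo, ci_high=hi,
        n_lineages=counts, boot_var=bvar,
        rarefied_to=r_min, B=B, seed=seed,
    )


# -- series models ------------------------------------------------------------------


def _norm_logpdf(x, mu, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _series_nll(model, params, x, t, sv):
    """Negative log likelihood of one series model.

    ``x`` values at times ``t`` (increasing toward the present, myr),
    ``sv`` per-point sampling variances. All models except Stasis condition
    on the first observation.
    """
    dt = np.diff(t)
    dx = np.diff(x)
    meas = sv[1:] + sv[:-1]
    if model == "BM":
        (ls,) = params
        var = np.exp(ls) * dt + meas
        return -_norm_logpdf(dx, 0.0, var).sum()
    if model == "Trend":
        mu, ls = params
        var = np.exp(ls) * dt + meas
        return -_norm_logpdf(dx, mu * dt, var).sum()
    if model == "Stasis":
        theta, lw = params
        var = np.exp(lw) + sv
        return -_norm_logpdf(x, theta, var).sum()
    if model == "OU":
        theta, la, ls = params
        alpha = np.exp(la)
        decay = np.exp(-alpha * dt)
        mean = theta + (x[:-1] - theta) * decay
        var = np.exp(ls) / (2 * alpha) * (1 - decay**2) + meas
        return -_norm_logpdf(x[1:], mean, var).sum()
    if model == "EB":
        ls, r = params
        # rate decays exponentially from the start of the series; r <= 0
        tm = 0.5 * (t[1:] + t[:-1]) - t[0]
        var = np.exp(ls) * np.exp(r * tm) * dt + meas
        return -_norm_logpdf(dx, 0.0, var).sum()
    raise ValueError(f"unknown series model {model!r}")


def _fit_one(model, x, t, sv):
    step_var = max(np.var(np.diff(x)) / max(np.mean(np.diff(t)), 1e-9), 1e-8)
    ls0 = np.log(step_var)
    inits = {
        "BM": [np.array([ls0])],
        "Trend": [np.array([np.polyfit(t, x, 1)[0], ls0])],
        "Stasis": [np.array([x.mean(), np.log(max(x.var(), 1e-8))])],
        "OU": [
            np.array([x.mean(), np.log(0.1), ls0]),
            np.array([x.mean(), np.log(1.0), ls0]),
        ],
        "EB": [np.array([ls0, -0.01]), np.array([ls0, -0.2])],
    }[model]
    bounds = {
        "BM": [(-30, 30)],
        "Trend": [(None, None), (-30, 30)],
        "Stasis": [(None, None), (-30, 30)],
        "OU": [(None, None), (-10, 10), (-30, 30)],
        "EB": [(-30, 30), (None, 0.0)],
    }[model]
    best = None
    for x0 in inits:
        res = minimize(
            lambda p: _series_nll(model, p, x, t, sv),
            x0, method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    names = {
        "BM": ["sigma2_step"],
        "Trend": ["mu", "sigma2_step"],
        "Stasis": ["theta", "omega"],
        "OU": ["theta", "alpha", "sigma2_step"],
        "EB": ["sigma2_step", "r"],
    }[model]
    raw = best.x
    params = {}
    for nm, v in zip(names, raw):
        params[nm] = float(np.exp(v)) if nm in ("sigma2_step", "omega", "alpha") else float(v)
    k = len(names)
    n = len(x) if model == "Stasis" else len(x) - 1
    ll = -float(best.fun)
    denom = n - k - 1
    aicc = 2 * k - 2 * ll + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
    return SeriesModelFit(
        model=model, params=params, log_likelihood=ll,
        n_params=k, n_obs=n, aicc=float(aicc),
    )


def fit_series_models(curve_or_series, times=None, sampling_var=None,
                      models=SERIES_MODELS):
    """Fit the five macroevolutionary models to a disparity series.

    Accepts a :class:`DisparityCurve` (usable bins only; times are bin
    midpoints converted to elapsed myr, sampling variances from the
    bootstrap) or a plain value array with explicit ``times``. Returns fits
    sorted by AICc with Akaike weights over the fitted set.
    """
    if isinstance(curve_or_series, DisparityCurve):
        use = curve_or_series.usable()
        x = curve_or_series.point[use]
        mids = np.array([0.5 * (b[0] + b[1]) for b in curve_or_series.bins])[use]
        t = mids.max() - mids  # elapsed time since the oldest usable bin
        sv = (
            curve_or_series.boot_var[use]
            if curve_or_series.boot_var is not None
            else np.zeros_like(x)
        )
    else:
        x = np.asarray(curve_or_series, dtype=float)
        if times is None:
            raise ValueError("times required for a plain series")
        t = np.asarray(times, dtype=float)
        sv = (
            np.asarray(sampling_var, dtype=float)
            if sampling_var is not None
            else np.zeros_like(x)
        )
    if len(x) < 5:
        raise ValueError("need at least 5 usable bins to fit series models")
    if not (np.isfinite(x).all() and np.isfinite(t).all()):
        raise ValueError("non-finite values in series")
    order = np.argsort(t)
    x, t, sv = x[order], t[order], sv[order]
    fits = [_fit_one(m, x, t, sv) for m in models]
    aiccs = np.array([f.aicc for f in fits])
    rel = np.exp(-0.5 * (aiccs - aiccs.min()))
    weights = rel / rel.sum()
    for f, w in zip(fits, weights):
        f.akaike_weight = float(w)
    return sorted(fits, key=lambda f: f.aicc)


def series_fit_table(fits):
    """Model-comparison table (model, logL, AICc, weight, parameters)."""
    return pd.DataFrame([f.summary_row() for f in fits])
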