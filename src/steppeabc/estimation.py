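"""ABC parameter estimation: rejection sampling + local-linear adjustment.

Given the reference-table rows of one model and an observed summary vector,
the closest simulations in z-scored Euclidean statistic distance are
retained; a weighted local-linear regression of the (transformed) parameter
on the statistics then adjusts each accepted value to the observed point
(Beaumont-style), with Epanechnikov kernel weights in distance.  Admixture
proportions are regressed on the logit scale and back-transformed, keeping
the posterior inside [0, 1].  The regression R-squared is reported as the
power diagnostic: a low value means the statistics carry little information
about the parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger("steppeabc.estimation")


class EstimationError(ValueError):
    pass


@dataclass
class AcceptedSet:
    """The rejection step's output: nearest rows and their distances."""

    rows: pd.DataFrame  # accepted reference rows (params + stats)
    distances: np.ndarray  # z-scored Euclidean distance, ascending
    stat_columns: tuple[str, ...]
    obs: pd.Series
    dropped_stats: tuple[str, ...] = ()


def rejection_sample(
    rows: pd.DataFrame,
    obs: pd.Series,
    n_keep: int,
    stat_columns: Sequence[str],
) -> AcceptedSet:
    """Keep the ``n_keep`` simulations closest to ``obs``.

    Distance is Euclidean over statistics z-scored by the table's per-stat
    standard deviation; zero-variance statistics are dropped with a warning.
    Deterministic: ties are broken by row order.
    """
    if n_keep > len(rows):
        raise EstimationError(f"n_keep={n_keep} exceeds table size {len(rows)}")
    X = rows[list(stat_columns)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(c for c, k in zip(stat_columns, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropping zero-variance statistics from distance: {dropped}",
            stacklevel=2,
        )
    used = [c for c, k in zip(stat_columns, keep) if k]
    obs_vec = obs[used].to_numpy(dtype=float)
    Z = (X[:, keep] - obs_vec) / sd[keep]
    d = np.sqrt((Z**2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_keep]
    return AcceptedSet(
        rows=rows.iloc[order].reset_index(drop=True),
        distances=d[order],
        stat_columns=tuple(used),
        obs=obs,
        dropped_stats=dropped,
    )


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PosteriorSample:
    """Raw and regression-adjusted posterior draws for one parameter."""

    parameter: str
    raw: np.ndarray
    adjusted: np.ndarray
    weights: np.ndarray
    r_squared: float
    transform: str = "identity"

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise EstimationError("weights must be finite and non-negative")


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel on distance, bandwidth = the largest accepted
    distance.  All-equal distances (including all-zero) give equal weights."""
    d_max = distances.max() if len(distances) else 0.0
    if d_max == 0:
        return np.ones_like(distances)
    w = 1.0 - (distances / d_max) ** 2
    # the boundary row(s) would get weight 0; keep them infinitesimally in
    w = np.maximum(w, 1e-12)
    return w


def regression_adjust(
    accepted: AcceptedSet,
    parameter: str,
    transform: str = "identity",
    ridge: float = 1e-8,
) -> PosteriorSample:
    """Local-linear adjustment of ``parameter`` toward the observed point.

    Fits a weighted linear model of the transformed parameter on the
    centred statistics; adjusted values are intercept + residuals, i.e.
    each accepted draw moved along the fitted plane to the observed
    statistics.  Falls back to a ridge solution when the local design is
    collinear.  ``transform``: 'identity', 'logit' (proportions) or 'log'.
    """
    if len(accepted.rows) < 50:
        raise EstimationError("need >= 50 accepted rows for the regression")
    theta = accepted.rows[parameter].to_numpy(dtype=float)
    if transform == "logit":
        y = _logit(theta)
    elif transform == "log":
        y = np.log(theta)
    elif transform == "identity":
        y = theta.copy()
    else:
        raise EstimationError(f"unknown transform {transform!r}")

    X = accepted.rows[list(accepted.stat_columns)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    used = sd > 0
    obs_vec = accepted.obs[list(accepted.stat_columns)].to_numpy(dtype=float)
    Xc = (X[:, used] - obs_vec[used]) / sd[used]

    w = epanechnikov_weights(accepted.distances)
    sw = np.sqrt(w)
    design = np.column_stack([np.ones(len(y)), Xc])
    A = design * sw[:, None]
    b = y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < design.shape[1]:
        # exact duplicates in the panel (e.g. Pi = pi * L) make the local
        # design rank-deficient; a small ridge keeps the solve well posed
        logger.info(
            "collinear statistics in local regression (rank %d < %d); "
            "using ridge fallback", rank, design.shape[1],
        )
        AtA = A.T @ A + ridge * np.eye(design.shape[1])
        coef = np.linalg.solve(AtA, A.T @ b)
    fitted = design @ coef
    resid = y - fitted
    y_adj = coef[0] + resid

    wbar = np.average(y, weights=w)
    ss_tot = np.sum(w * (y - wbar) ** 2)
    ss_res = np.sum(w * resid**2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    if transform == "logit":
        adjusted = _expit(y_adj)
    elif transform == "log":
        adjusted = np.exp(y_adj)
    else:
        adjusted = y_adj
    return PosteriorSample(
        parameter=parameter,
        raw=theta,
        adjusted=adjusted,
        weights=w,
        r_squared=r2,
        transform=transform,
    )


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> np.ndarray | float:
    """Weighted quantile(s) by cumulative-weight interpolation.

    The weighted CDF steps by w_i/W at each sorted value; a quantile falling
    strictly inside a step returns that value, and one landing exactly on a
    step boundary returns the midpoint of the adjacent values (so the
    weighted median of {(0.1, 1), (0.2, 1), (0.9, 2)} is 0.55).
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w) / w.sum()
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty_like(qs)
    for i, qq in enumerate(qs):
        j = int(np.searchsorted(cum, qq, side="left"))
        if j >= len(v):
            out[i] = v[-1]
        elif j + 1 < len(v) and np.isclose(cum[j], qq):
            out[i] = 0.5 * (v[j] + v[j + 1])
        else:
            out[i] = v[j]
    return out if np.ndim(q) else float(out[0])


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    return float(weighted_quantile(values, weights, 0.5))


@dataclass
class PointEstimates:
    parameter: str
    median: float
    mode: float
    mean: float
    ci_low: float
    ci_high: float
    r_squared: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "parameter": self.parameter,
                "median": self.median,
                "mode": self.mode,
                "mean": self.mean,
                "ci95_low": self.ci_low,
                "ci95_high": self.ci_high,
                "R2": self.r_squared,
            }
        )


def point_estimates(
    ps: PosteriorSample, ci_level: float = 0.95, grid_size: int = 512
) -> PointEstimates:
    """Weighted median, KDE mode (Silverman bandwidth), mean and equal-tail
    credible interval of the adjusted posterior sample."""
    v = np.asarray(ps.adjusted, dtype=float)
    w = np.asarray(ps.weights, dtype=float)
    if len(v) == 0:
        raise EstimationError("empty posterior sample")
    if np.allclose(v, v[0]):
        x = float(v[0])
        return PointEstimates(ps.parameter, x, x, x, x, x, ps.r_squared)
    med = weighted_median(v, w)
    mean = float(np.average(v, weights=w))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = weighted_quantile(v, w, np.array([alpha, 1.0 - alpha]))
    kde = gaussian_kde(v, bw_method="silverman", weights=w)
    grid = np.linspace(v.min(), v.max(), grid_size)
    mode = float(grid[np.argmax(kde(grid))])
    return PointEstimates(ps.parameter, med, mode, mean, float(lo), float(hi), ps.r_squared)


def estimate_parameter(
    rows: pd.DataFrame,
    obs: pd.Series,
    parameter: str,
    stat_columns: Sequence[str],
    n_keep: int,
    transform: str = "identity",
) -> tuple[PosteriorSample, PointEstimates]:
    """Convenience wrapper: rejection, adjustment, point estimates."""
    acc = rejection_sample(rows, obs, n_keep, stat_columns)
    ps = regression_adjust(acc, parameter, transform=transform)
    return ps, point_estimates(ps)
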