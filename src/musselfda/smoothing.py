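"""Nonparametric functional representation of longitudinal trajectories.

Each individual's sparse, possibly gappy series of monthly measurements is
turned into a smooth curve by Nadaraya-Watson kernel regression

    X(t) = sum_j y_j K_h(t - t_j) / sum_j K_h(t - t_j)

with a Gaussian kernel K_h(u) = K(u/h)/h and a per-individual bandwidth h
chosen by generalized cross-validation (GCV).  The estimator is a convex
combination of the observations, so every smoothed value lies within the
observed range — a property the tests assert.

The sklearn-style :class:`NadarayaWatsonSmoother` is the primary interface;
:func:`nw_smooth`, :func:`gcv_bandwidth` and :func:`build_functional_sample`
are thin functional wrappers kept for pipeline and interactive use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "FunctionalSample",
    "nw_smooth",
    "gcv_bandwidth",
    "default_bandwidth_grid",
    "build_functional_sample",
    "NadarayaWatsonSmoother",
]


@dataclass
class Trajectory:
    """One individual's discrete observations of one variable over time.

    ``t`` in days since experiment start, strictly increasing; ``y`` may
    contain NaN for missing samplings (dropped from the smoothing sums, no
    imputation).
    """

    individual_id: object
    variable: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.y).sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.y)
        return self.t[ok], self.y[ok]


@dataclass
class FunctionalSample:
    """A set of smoothed curves on a common evaluation grid.

    ``curves`` has one row per individual, in input order; ``bandwidths``
    records the GCV-selected h per curve.
    """

    grid: np.ndarray
    curves: np.ndarray
    bandwidths: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        self.ids = list(self.ids)
        if self.curves.shape != (len(self.ids), self.grid.size):
            raise ValueError("curves must be (n_ids, n_grid)")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.bandwidths <= 0):
            raise ValueError("bandwidths must be positive")

    @property
    def n(self) -> int:
        return self.curves.shape[0]

    def subset(self, keep_ids) -> "FunctionalSample":
        keep = set(keep_ids)
        idx = [i for i, j in enumerate(self.ids) if j in keep]
        return FunctionalSample(
            self.grid, self.curves[idx], self.bandwidths[idx],
            [self.ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: id column then one column per grid point."""
        df = pd.DataFrame(self.curves, columns=[f"t{g:g}" for g in self.grid])
        df.insert(0, "individual_id", self.ids)
        return df

    def save(self, csv_path, meta_path, **meta) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        payload = {
            "grid": self.grid.tolist(),
            "bandwidths": self.bandwidths.tolist(),
            "ids": [str(i) for i in self.ids],
            **meta,
        }
        with open(meta_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _nw_weights(t_obs: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    """(n_grid, n_obs) normalized Gaussian kernel weights.

    Computed on the log scale and shifted by the row max so that evaluation
    points far from every observation do not underflow to 0/0.
    """
    u = (grid[:, None] - t_obs[None, :]) / h
    logw = -0.5 * u * u
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def nw_smooth(traj: Trajectory, h: float, grid) -> np.ndarray:
    """Evaluate the Nadaraya-Watson estimate of one trajectory on ``grid``."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    t_obs, y_obs = traj.observed()
    if t_obs.size == 0:
        raise ValueError(f"trajectory {traj.individual_id!r} has no data")
    grid = np.asarray(grid, dtype=float)
    return _nw_weights(t_obs, h, grid) @ y_obs


def default_bandwidth_grid(t_obs: np.ndarray, n_candidates: int = 25) -> np.ndarray:
    """Log-spaced candidates from half the minimum time gap to the span."""
    t_obs = np.asarray(t_obs, dtype=float)
    if t_obs.size < 2:
        raise ValueError("need at least two observation times")
    lo = 0.5 * np.diff(np.sort(t_obs)).min()
    hi = t_obs.max() - t_obs.min()
    return np.geomspace(lo, hi, n_candidates)


def gcv_score(traj: Trajectory, h: float) -> float:
    """GCV(h) = mean(((y - S_h y) / (1 - tr(S_h)/n))^2) on the observed times."""
    t_obs, y_obs = traj.observed()
    n = t_obs.size
    S = _nw_weights(t_obs, h, t_obs)
    resid = y_obs - S @ y_obs
    denom = 1.0 - np.trace(S) / n
    if denom <= 0:
        return np.inf
    return float(np.mean((resid / denom) ** 2))


def gcv_bandwidth(traj: Trajectory, candidates=None) -> float:
    """Pick the GCV-minimizing bandwidth from ``candidates``.

    Ties (within a 1e-9 relative band, e.g. noiseless constant data where
    every h fits perfectly) are broken toward the largest — smoothest —
    candidate.
    """
    if traj.n_valid < 3:
        raise ValueError(
            f"trajectory {traj.individual_id!r} needs >= 3 observed points"
        )
    if candidates is None:
        candidates = default_bandwidth_grid(traj.observed()[0])
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0 or np.any(candidates <= 0):
        raise ValueError("bandwidth candidates must be positive and non-empty")
    scores = np.array([gcv_score(traj, h) for h in candidates])
    if not np.any(np.isfinite(scores)):
        raise ValueError(
            f"GCV non-finite for all candidates on trajectory "
            f"{traj.individual_id!r}"
        )
    best = np.nanmin(scores[np.isfinite(scores)])
    tol = 1e-9 * max(1.0, abs(best))
    tied = np.where(np.isfinite(scores) & (scores <= best + tol))[0]
    return float(candidates[tied[-1]])


class NadarayaWatsonSmoother(BaseEstimator, TransformerMixin):
    """Smooth a collection of trajectories onto a common grid.

    Parameters
    ----------
    grid_size : number of equispaced evaluation points spanning the shared
        time range of the fitted trajectories.
    bandwidth : 'gcv' for per-curve generalized cross-validation, or a fixed
        positive float applied to every curve.
    n_candidates : size of the log-spaced GCV search grid.
    min_points : trajectories with fewer observed points are excluded (and
        listed in ``skipped_``) rather than unreliably smoothed.

    Attributes (after fit)
    ----------------------
    grid_ : common evaluation grid (days).
    bandwidths_ : selected h per retained trajectory.
    ids_ : retained trajectory ids, input order.
    skipped_ : list of (id, reason) for excluded trajectories.
    """

    def __init__(self, grid_size: int = 101, bandwidth="gcv",
                 n_candidates: int = 25, min_points: int = 3):
        self.grid_size = grid_size
        self.bandwidth = bandwidth
        self.n_candidates = n_candidates
        self.min_points = min_points

    def fit(self, trajectories, y=None):
        trajs, skipped = [], []
        for tr in trajectories:
            if tr.n_valid < self.min_points:
                skipped.append(
                    (tr.individual_id,
                     f"only {tr.n_valid} observed points (< {self.min_points})")
                )
                logger.warning("skipping trajectory %r: %s", *skipped[-1])
            else:
                trajs.append(tr)
        if len(trajs) < 2:
            raise ValueError("need at least two smoothable trajectories")
        variables = {tr.variable for tr in trajs}
        if len(variables) > 1:
            raise ValueError(f"mixed variables in one sample: {variables}")
        t_lo = min(tr.observed()[0].min() for tr in trajs)
        t_hi = max(tr.observed()[0].max() for tr in trajs)
        self.grid_ = np.linspace(t_lo, t_hi, self.grid_size)
        if self.bandwidth == "gcv":
            self.bandwidths_ = np.array([
                gcv_bandwidth(
                    tr, default_bandwidth_grid(tr.observed()[0], self.n_candidates)
                )
                for tr in trajs
            ])
        else:
            h = float(self.bandwidth)
            if h <= 0:
                raise ValueError("fixed bandwidth must be positive")
            self.bandwidths_ = np.full(len(trajs), h)
        self.ids_ = [tr.individual_id for tr in trajs]
        self.skipped_ = skipped
        self._trajs = trajs
        return self

    def transform(self, trajectories=None) -> FunctionalSample:
        """Evaluate the fitted curves; returns a :class:`FunctionalSample`.

        ``trajectories`` defaults to the fitted collection (the usual case:
        the smoother is fitted and applied to the same cohort).
        """
        if not hasattr(self, "grid_"):
            raise ValueError("smoother is not fitted")
        trajs = self._trajs if trajectories is None else [
            tr for tr in trajectories if tr.n_valid >= self.min_points
        ]
        curves = np.vstack([
            nw_smooth(tr, h, self.grid_)
            for tr, h in zip(trajs, self.bandwidths_)
        ])
        return FunctionalSample(self.grid_, curves, self.bandwidths_,
                                [tr.individual_id for tr in trajs])


def build_functional_sample(
    trajectories, grid_size: int = 101, bandwidth="gcv", n_candidates: int = 25,
) -> tuple[FunctionalSample, list]:
    """Smooth a trajectory collection; returns (sample, skip_report)."""
    sm = NadarayaWatsonSmoother(
        grid_size=grid_size, bandwidth=bandwidth, n_candidates=n_candidates
    ).fit(trajectories)
    return sm.transform(None), sm.skipped_


def trajectories_from_frame(df: pd.DataFrame, variable: str) -> list[Trajectory]:
    """Extract one :class:`Trajectory` per individual from a long table."""
    out = []
    for iid, g in df.sort_values("t").groupby("individual_id", sort=False):
        out.append(Trajectory(iid, variable,
                              g["t"].to_numpy(dtype=float),
                              g[variable].to_numpy(dtype=float)))
    return out
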