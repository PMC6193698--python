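"""Functional depth diagnostics: h-modal depth, trimmed-mode outlier
detection, and bootstrap confidence bands for mean curves.

The h-modal depth of a curve x_i in a sample {x_1..x_n} is

    depth(x_i) = sum_j K( ||x_i - x_j||_2 / h_d )

with K Gaussian and ||.||_2 the L2 norm by trapezoid quadrature on the common
grid; h_d defaults to the 15th percentile of the pairwise distances.  Deep
curves sit near the functional mode; outliers have low depth.

Outlier detection follows the trimmed-bootstrap scheme: a cutoff is the
median over B smoothed-bootstrap replicates (resampled from the (1-trim)
deepest curves) of the 1% depth quantile, curves below it are flagged and
removed, and the procedure iterates until no new flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "DepthResult",
    "l2_distance_matrix",
    "modal_depth",
    "ModalDepthOutlierDetector",
    "trimmed_mode_outliers",
    "functional_mean",
    "bootstrap_band",
]


def _quad_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for the (possibly non-uniform) grid."""
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def l2_distance_matrix(curves: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Pairwise L2 distances between curve rows under trapezoid quadrature."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    w = _quad_weights(grid)
    cw = curves * w  # weighted once; <x_i, x_j>_w = curves @ cw.T
    gram = curves @ cw.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - gram - gram.T
    return np.sqrt(np.maximum(d2, 0.0))


def modal_depth(curves: np.ndarray, grid: np.ndarray, h_d: float | None = None,
                dist: np.ndarray | None = None) -> np.ndarray:
    """h-modal depth of every curve row; all-identical samples get equal depths."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[0] < 2:
        raise ValueError("need at least two curves")
    if dist is None:
        dist = l2_distance_matrix(curves, grid)
    if h_d is None:
        off = dist[~np.eye(dist.shape[0], dtype=bool)]
        h_d = float(np.percentile(off, 15))
        if h_d <= 0 and np.any(off > 0):
            h_d = float(off[off > 0].min())  # ties at 0 below the 15th pctile
    if h_d <= 0:
        # degenerate sample (all curves identical): equal depth by symmetry
        return np.full(curves.shape[0], float(curves.shape[0]))
    u = dist / h_d
    return np.exp(-0.5 * u * u).sum(axis=1) / np.sqrt(2 * np.pi)


class ModalDepthOutlierDetector(BaseEstimator):
    """Iterative trimmed-mode functional outlier detector.

    Parameters
    ----------
    trim : trimmed-mode fraction — the central-tendency estimate
        ``center_`` is the mean of the deepest (1 - trim) curves.
    B : bootstrap replicates per iteration (warns below 100).
    alpha_cut : depth quantile recorded per replicate; the cutoff is the
        median of these over the B replicates.
    smooth_frac : sd of the smoothed-bootstrap noise as a fraction of the
        pointwise sd of the curves.  The default 0.4 is calibrated so that
        bootstrap replicates regenerate the tails of a homogeneous sample,
        keeping the null flag rate near ``alpha_cut``; much smaller noise
        makes the cutoff anti-conservative by an order of magnitude.
    max_iter : iteration cap; non-convergence stops with a warning.
    random_state : seed making the whole procedure deterministic.

    Attributes (after fit)
    ----------------------
    depths_ : modal depths of all curves in the full sample.
    cutoff_ : first-iteration bootstrap cutoff.
    outlier_mask_ : boolean flag per input curve.
    n_iter_ : iterations performed.
    """

    def __init__(self, trim: float = 0.1, B: int = 500, alpha_cut: float = 0.01,
                 smooth_frac: float = 0.4, max_iter: int = 5,
                 random_state: int | None = None):
        self.trim = trim
        self.B = B
        self.alpha_cut = alpha_cut
        self.smooth_frac = smooth_frac
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, grid=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if n < 10:
            raise ValueError("outlier detection needs at least 10 curves")
        if not 0 < self.trim < 0.5:
            raise ValueError("trim must lie in (0, 0.5)")
        if self.B < 100:
            warnings.warn("B < 100 bootstrap replicates: cutoff is unstable",
                          UserWarning, stacklevel=2)
        grid = np.arange(X.shape[1], dtype=float) if grid is None else np.asarray(grid, float)
        rng = np.random.default_rng(self.random_state)

        active = np.arange(n)
        flagged: list[int] = []
        self.cutoffs_ = []
        for it in range(self.max_iter):
            cur = X[active]
            dist = l2_distance_matrix(cur, grid)
            off = dist[~np.eye(dist.shape[0], dtype=bool)]
            h_d = float(np.percentile(off, 15))
            if h_d <= 0 and np.any(off > 0):
                h_d = float(off[off > 0].min())
            depths = modal_depth(cur, grid, h_d=h_d, dist=dist)
            if it == 0:
                self.depths_ = depths.copy()
                order = np.argsort(depths)[::-1]
                keep = max(2, int(np.ceil((1 - self.trim) * len(active))))
                self.center_ = cur[order[:keep]].mean(axis=0)
            if np.all(cur.std(axis=0) == 0):
                # identical curves: nothing can be an outlier
                self.cutoffs_.append(0.0)
                break
            noise_sd = self.smooth_frac * cur.std(axis=0, ddof=1)
            qs = np.empty(self.B)
            for b in range(self.B):
                idx = rng.integers(0, len(active), size=len(active))
                boot = cur[idx] + rng.normal(0, 1, size=cur.shape) * noise_sd
                # depth on the sample's own distance scale, so the bootstrap
                # quantile is comparable to the observed depths
                qs[b] = np.quantile(modal_depth(boot, grid, h_d=h_d),
                                    self.alpha_cut, method="lower")
            cutoff = float(np.median(qs))
            self.cutoffs_.append(cutoff)
            new = active[depths < cutoff]
            if new.size == 0:
                break
            flagged.extend(new.tolist())
            active = np.setdiff1d(active, new)
            if active.size < 10:
                warnings.warn("fewer than 10 curves remain; stopping",
                              UserWarning, stacklevel=2)
                break
        else:
            warnings.warn(f"outlier iteration did not settle in "
                          f"{self.max_iter} passes", UserWarning, stacklevel=2)
        self.n_iter_ = len(self.cutoffs_)
        self.cutoff_ = self.cutoffs_[0]
        self.outlier_mask_ = np.zeros(n, dtype=bool)
        self.outlier_mask_[flagged] = True
        return self

    def predict(self, X=None):
        """sklearn outlier convention: -1 for outliers, +1 for inliers."""
        return np.where(self.outlier_mask_, -1, 1)


@dataclass
class DepthResult:
    """Depths, bootstrap cutoff and flagged ids from outlier detection."""

    depths: np.ndarray
    cutoff: float
    outlier_ids: list
    B: int
    seed: int | None

    def to_frame(self, ids):
        import pandas as pd
        return pd.DataFrame({
            "individual_id": list(ids),
            "depth": self.depths,
            "outlier": [i in set(self.outlier_ids) for i in ids],
        })


def trimmed_mode_outliers(fs, trim: float = 0.1, B: int = 500,
                          alpha_cut: float = 0.01, seed: int | None = None,
                          smooth_frac: float = 0.4) -> DepthResult:
    """Run :class:`ModalDepthOutlierDetector` on a functional sample."""
    det = ModalDepthOutlierDetector(
        trim=trim, B=B, alpha_cut=alpha_cut, smooth_frac=smooth_frac,
        random_state=seed,
    ).fit(fs.curves, grid=fs.grid)
    outlier_ids = [fs.ids[i] for i in np.flatnonzero(det.outlier_mask_)]
    return DepthResult(det.depths_, det.cutoff_, outlier_ids, B, seed)


def functional_mean(fs) -> np.ndarray:
    """Pointwise mean curve of a functional sample."""
    if fs.n < 1:
        raise ValueError("empty sample")
    return fs.curves.mean(axis=0)


def bootstrap_band(fs, B: int = 500, level: float = 0.95,
                   seed: int | None = None):
    """Uniform (sup-norm) bootstrap confidence band for the mean curve.

    Returns ``(lower, upper)``; the band is the observed mean plus/minus the
    ``level`` quantile of sup-norm deviations of B resampled means, so it
    contains the observed mean everywhere by construction.
    """
    if fs.n < 2:
        raise ValueError("need at least two curves")
    if B < 200:
        warnings.warn("B < 200: band quantile is unstable", UserWarning,
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    mean = fs.curves.mean(axis=0)
    idx = rng.integers(0, fs.n, size=(B, fs.n))
    boot_means = fs.curves[idx].mean(axis=1)
    sup = np.abs(boot_means - mean).max(axis=1)
    r = float(np.quantile(sup, level))
    return mean - r, mean + r
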