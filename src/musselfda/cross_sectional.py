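"""Cross-sectional (per-sampling) distribution and homogeneity statistics.

Covers the sampling-by-sampling analyses of the cohort: plug-in-bandwidth
kernel density fits of the size distribution, rank-based one-way ANOVA
(Kruskal-Wallis) with Tukey-HSD post hoc on ranks, and a PERMDISP-style
permutation test for homogeneity of dispersions (ANOVA-F on distances of
observations to their group centroid, inference by permuting the distances).

Repeated measures of the same individuals at different samplings are treated
as independent groups here, as is conventional for these tests; the
functional machinery in :mod:`musselfda.depth` and :mod:`musselfda.groups`
is what actually respects the longitudinal structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "TestResult",
    "plugin_bandwidth",
    "PluginKDE",
    "kde_plugin",
    "kruskal_wallis",
    "tukey_hsd_on_ranks",
    "dispersion_test",
]


@dataclass
class TestResult:
    """Uniform container for every hypothesis test in the package."""

    method: str
    statistic: float
    p_value: float
    n_resamples: int | None = None
    seed: int | None = None
    groups: list = field(default_factory=list)
    details: object = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# plug-in KDE

_SQRT_2PI = np.sqrt(2 * np.pi)


def _phi_deriv_sum(x: np.ndarray, g: float, order: int) -> float:
    """n^-2 sum_ij K_g^(order)(x_i - x_j), Gaussian kernel, exact pairwise."""
    u = (x[:, None] - x[None, :]) / g
    if order == 4:
        poly = u**4 - 6 * u**2 + 3
    elif order == 6:
        poly = u**6 - 15 * u**4 + 45 * u**2 - 15
    else:  # pragma: no cover
        raise ValueError(order)
    k = poly * np.exp(-0.5 * u * u) / _SQRT_2PI
    return float(k.sum()) / (x.size**2 * g ** (order + 1))


def plugin_bandwidth(values) -> float:
    """Two-stage direct plug-in (Sheather-Jones family) bandwidth.

    Starts from the normal-scale estimate of the 8th-derivative functional,
    refines the 6th and 4th through kernel functional estimates, and returns
    h = (R(K) / (psi_4 n))^(1/5) for the Gaussian kernel.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 finite observations")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(x.std(ddof=1), iqr / 1.349) if iqr > 0 else x.std(ddof=1)
    if sigma <= 0:
        raise ValueError("zero-variance sample: bandwidth undefined")
    # normal-scale psi_8 = 105 / (32 sqrt(pi) sigma^9)
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sigma**9)
    # stage 1: psi_6 via pilot g6 = (2 K^(6)(0) / (-mu2 psi8 n))^(1/9)
    k6_0 = -15.0 / _SQRT_2PI
    g6 = (2.0 * abs(k6_0) / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _phi_deriv_sum(x, g6, 6)
    # stage 2: psi_4 via g4 = (2 K^(4)(0) / (-mu2 psi6 n))^(1/7); psi6 < 0
    k4_0 = 3.0 / _SQRT_2PI
    g4 = (2.0 * k4_0 / (-psi6 * n)) ** (1.0 / 7.0)
    psi4 = _phi_deriv_sum(x, g4, 4)
    # h = (R(K) / (mu2^2 psi4 n))^(1/5), R(K) = 1/(2 sqrt(pi)), mu2 = 1
    return float((1.0 / (2.0 * np.sqrt(np.pi) * psi4 * n)) ** 0.2)


class PluginKDE(BaseEstimator):
    """Gaussian KDE with Sheather-Jones-type direct plug-in bandwidth.

    Attributes after fit: ``bandwidth_``, ``grid_``, ``density_``.
    """

    def __init__(self, grid_size: int = 512, cut: float = 3.0):
        self.grid_size = grid_size
        self.cut = cut

    def fit(self, values, y=None):
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        self.bandwidth_ = plugin_bandwidth(x)
        self._x = x
        lo = x.min() - self.cut * self.bandwidth_
        hi = x.max() + self.cut * self.bandwidth_
        self.grid_ = np.linspace(lo, hi, self.grid_size)
        self.density_ = self.evaluate(self.grid_)
        return self

    def evaluate(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        u = (grid[:, None] - self._x[None, :]) / self.bandwidth_
        return np.exp(-0.5 * u * u).sum(axis=1) / (
            self._x.size * self.bandwidth_ * _SQRT_2PI
        )


def kde_plugin(values, grid_size: int = 512):
    """Density estimate on an automatic grid; returns (grid, density, h)."""
    kde = PluginKDE(grid_size=grid_size).fit(values)
    return kde.grid_, kde.density_, kde.bandwidth_


# ---------------------------------------------------------------------------
# rank-based homogeneity tests


def kruskal_wallis(*groups) -> TestResult:
    """One-way ANOVA by ranks (Kruskal-Wallis H, mid-rank tie correction)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal-wallis", 0.0, 1.0,
                          groups=list(range(len(groups))))
    h, p = stats.kruskal(*arrs)
    return TestResult("kruskal-wallis", float(h), float(p),
                      groups=list(range(len(groups))))


def tukey_hsd_on_ranks(*groups, on: str = "ranks",
                       labels=None) -> pd.DataFrame:
    """All-pairs Tukey-HSD, by default on the pooled mid-ranks.

    Groups of size 1 are excluded with a warning.  Returns a symmetric tidy
    table (group_1, group_2, statistic = mean difference on the analysed
    scale, p_value).
    """
    labels = list(labels) if labels is not None else list(range(len(groups)))
    arrs = [np.asarray(g, dtype=float) for g in groups]
    keep = [i for i, a in enumerate(arrs) if a.size >= 2]
    if len(keep) < len(arrs):
        warnings.warn("groups with n < 2 excluded from Tukey-HSD",
                      UserWarning, stacklevel=2)
    arrs = [arrs[i] for i in keep]
    labels = [labels[i] for i in keep]
    if len(arrs) < 2:
        raise ValueError("need at least two groups of size >= 2")
    if on == "ranks":
        pooled = stats.rankdata(np.concatenate(arrs))
        split = np.split(pooled, np.cumsum([a.size for a in arrs])[:-1])
    elif on == "raw":
        split = arrs
    else:
        raise ValueError("on must be 'ranks' or 'raw'")
    res = stats.tukey_hsd(*split)
    rows = []
    for i in range(len(split)):
        for j in range(len(split)):
            if i == j:
                continue
            rows.append({
                "group_1": labels[i], "group_2": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p_value": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMDISP-style dispersion homogeneity test


def _anova_f(z: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> float:
    """One-way ANOVA F for already-grouped contiguous data."""
    n = z.size
    k = sizes.size
    grand = z.mean()
    means = np.add.reduceat(z, starts) / sizes
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float((z**2).sum() - (sizes * means**2).sum())
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def _centroid_distances(values: np.ndarray, codes: np.ndarray, k: int,
                        centroid: str) -> np.ndarray:
    z = np.empty(values.shape[0])
    for g in range(k):
        m = codes == g
        v = values[m]
        if centroid == "mean":
            c = v.mean(axis=0)
        elif centroid == "median":
            c = _spatial_median(v)
        else:
            raise ValueError("centroid must be 'mean' or 'median'")
        if values.ndim == 1:
            z[m] = np.abs(v - c)
        else:
            z[m] = np.sqrt(((v - c) ** 2).sum(axis=1))
    return z


def _spatial_median(v: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
    if v.ndim == 1:
        return np.median(v)
    c = v.mean(axis=0)
    for _ in range(max_iter):  # Weiszfeld iteration
        d = np.sqrt(((v - c) ** 2).sum(axis=1))
        d = np.where(d < tol, tol, d)
        new = (v / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.abs(new - c).max() < tol:
            return new
        c = new
    return c


def dispersion_test(values, groups, n_perm: int = 999,
                    seed: int | None = None, centroid: str = "mean",
                    post_hoc: bool = False) -> TestResult:
    """Distance-based homogeneity-of-dispersions test (PERMDISP-style).

    Each observation is reduced to its distance from its own group centroid
    (absolute deviation from the group mean for univariate data, Euclidean
    distance for multivariate); a one-way ANOVA F is computed on those
    distances and referred to a permutation null obtained by shuffling the
    distances among groups, p = (1 + #{F* >= F}) / (1 + n_perm).  Location
    differences between groups are invisible to the test by construction.

    With ``post_hoc=True`` the result's ``details`` carries a Tukey-HSD
    table on the distances.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 3:
        raise ValueError("each group needs at least 3 observations")
    if n_perm < 199:
        warnings.warn("n_perm < 199: permutation p-value is coarse",
                      UserWarning, stacklevel=2)

    z = _centroid_distances(values, codes, k, centroid)
    order = np.argsort(codes, kind="stable")
    z_sorted = z[order]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    f_obs = _anova_f(z_sorted, starts, sizes)
    if f_obs == 0.0 and z.std() == 0:
        # identical dispersions everywhere (e.g. constant groups)
        return TestResult("permdisp", 0.0, 1.0, n_perm, seed,
                          groups=labels.tolist())

    rng = np.random.default_rng(seed)
    count = 0
    zp = z_sorted.copy()
    for _ in range(n_perm):
        rng.shuffle(zp)
        if _anova_f(zp, starts, sizes) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    details = None
    if post_hoc:
        by_group = [z[codes == g] for g in range(k)]
        details = tukey_hsd_on_ranks(*by_group, on="raw", labels=labels.tolist())
    return TestResult("permdisp", float(f_obs), float(p), n_perm, seed,
                      groups=labels.tolist(), details=details)
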