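"""Fast/slow grower classification and between-group functional inference.

Individuals are split at the cohort median of final size (shell length L or
total fresh weight TFW): above-median individuals are "fast" growers,
below-median "slow", exact ties are excluded.  Group mean curves of growth
and of every scope-for-growth component are then compared with a one-way
functional ANOVA whose statistic is

    V = sum_{i<j} n_i || Xbar_i - Xbar_j ||_2^2

under the L2 grid-quadrature norm, with a parametric Gaussian-process
bootstrap null (group mean curves simulated from each group's estimated
covariance at its own sample size).  Dependence between two sets of curves
(e.g. growth vs. feeding) is assessed with a distance-covariance permutation
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_sectional import TestResult
from .depth import _quad_weights, bootstrap_band, functional_mean
from .smoothing import FunctionalSample, build_functional_sample, trajectories_from_frame

logger = logging.getLogger(__name__)

__all__ = [
    "GroupLabel",
    "select_even_start",
    "classify_growers",
    "fanova",
    "functional_correlation_test",
    "compare_groups_report",
    "REPORT_VARIABLES",
]

#: variables compared between growth groups, in report order
REPORT_VARIABLES = ["L", "TFW", "SFG", "CR", "OIR", "AE", "AR", "VO2", "VNH4"]


@dataclass(frozen=True)
class GroupLabel:
    """Fast/slow classification of one individual under a stated criterion."""

    individual_id: object
    criterion: str
    label: str  # "fast" | "slow"
    cutpoint: float


def select_even_start(records: pd.DataFrame, variable: str = "L",
                      target: float = 21.0, tolerance: float = 0.5,
                      precision: float = 0.1) -> list:
    """Ids whose first-sampling value is within ``target +/- tolerance``.

    Values are first rounded to the measurement ``precision`` (0.1 mm for
    shell length read off a caliper).  Deterministic; raises if nothing
    qualifies.
    """
    t0 = records["t"].min()
    first = records[records["t"] == t0]
    dec = max(0, int(round(-np.log10(precision))))
    vals = first[variable].to_numpy(dtype=float).round(dec)
    ok = np.abs(vals - target) <= tolerance + 1e-9
    ids = first.loc[ok, "individual_id"].tolist()
    if not ids:
        raise ValueError(
            f"no individuals with first-sampling {variable} within "
            f"{target} +/- {tolerance}; widen the tolerance"
        )
    return ids


def classify_growers(final_sizes: pd.Series, criterion: str):
    """Median split of final sizes into fast (> median) and slow (< median).

    Parameters
    ----------
    final_sizes : value at the last sampling, indexed by individual id.
    criterion : name recorded on each label (e.g. ``"L"`` or ``"TFW"``).

    Returns
    -------
    labels : list of :class:`GroupLabel` for classified individuals.
    excluded : ids lying exactly at the median (logged, not classified).
    """
    final_sizes = final_sizes.dropna()
    if len(final_sizes) < 4:
        raise ValueError("need at least 4 individuals with a final value")
    cut = float(np.median(final_sizes.to_numpy(dtype=float)))
    labels, excluded = [], []
    for iid, v in final_sizes.items():
        if v > cut:
            labels.append(GroupLabel(iid, criterion, "fast", cut))
        elif v < cut:
            labels.append(GroupLabel(iid, criterion, "slow", cut))
        else:
            excluded.append(iid)
    if excluded:
        logger.info("%d individuals at the median excluded: %s",
                    len(excluded), excluded)
    n_fast = sum(1 for l in labels if l.label == "fast")
    n_slow = len(labels) - n_fast
    if min(n_fast, n_slow) < 1:
        raise ValueError("median split left an empty group")
    return labels, excluded


def _group_matrices(fs: FunctionalSample, group_of: dict):
    by = {}
    for i, iid in enumerate(fs.ids):
        g = group_of.get(iid)
        if g is not None:
            by.setdefault(g, []).append(i)
    return {g: fs.curves[idx] for g, idx in by.items()}


def _v_from_means(means: dict, sizes: dict, grid: np.ndarray) -> float:
    """V = sum over group pairs i<j of n_i * ||mean_i - mean_j||_2^2.

    ``means[g]`` may be a single curve or a (B, n_grid) stack, in which case
    a vector of B statistics is returned.
    """
    w = _quad_weights(grid)
    keys = sorted(means, key=str)
    v = 0.0
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            d = means[keys[a]] - means[keys[b]]
            v = v + sizes[keys[a]] * (d * d * w).sum(axis=-1)
    return float(v) if np.ndim(v) == 0 else v


def fanova_statistic(group_curves: dict, grid: np.ndarray) -> float:
    """V statistic computed from raw per-group curve matrices."""
    means = {g: c.mean(axis=0) for g, c in group_curves.items()}
    sizes = {g: c.shape[0] for g, c in group_curves.items()}
    return _v_from_means(means, sizes, grid)


def fanova(fs: FunctionalSample, labels, B: int = 500,
           seed: int | None = None, method: str = "bootstrap") -> TestResult:
    """One-way functional ANOVA for equality of group mean curves.

    ``labels`` may be a list of :class:`GroupLabel` or a mapping id -> group.
    The null distribution of V is approximated either by a parametric
    bootstrap (``method='bootstrap'``: group mean curves drawn as zero-mean
    Gaussian processes with each group's estimated covariance divided by its
    sample size) or by permutation of the group labels
    (``method='permutation'``, a robustness alternative).
    p = (1 + #{V* >= V}) / (1 + B).
    """
    if B < 200:
        warnings.warn("B < 200 resamples: p-value is coarse", UserWarning,
                      stacklevel=2)
    group_of = (
        {l.individual_id: l.label for l in labels}
        if labels and isinstance(next(iter(labels)), GroupLabel)
        else dict(labels)
    )
    gm = _group_matrices(fs, group_of)
    if len(gm) < 2:
        raise ValueError("need at least two groups present in the sample")
    if any(c.shape[0] < 3 for c in gm.values()):
        raise ValueError("each group needs at least 3 curves")
    v_obs = fanova_statistic(gm, fs.grid)
    rng = np.random.default_rng(seed)
    keys = sorted(gm, key=str)
    if method == "bootstrap":
        # mean-curve draw: Xc' z / sqrt((n-1) n) has covariance Sigma_hat / n
        centered = {g: gm[g] - gm[g].mean(axis=0) for g in keys}
        sizes = {g: gm[g].shape[0] for g in keys}
        draws = {}
        for g in keys:
            n_g = sizes[g]
            z = rng.standard_normal((B, n_g))
            draws[g] = (z @ centered[g]) / np.sqrt((n_g - 1) * n_g)
        v_null = np.asarray(_v_from_means(draws, sizes, fs.grid))
    elif method == "permutation":
        all_curves = np.vstack([gm[g] for g in keys])
        sizes = [gm[g].shape[0] for g in keys]
        edges = np.cumsum(sizes)[:-1]
        v_null = np.empty(B)
        for b in range(B):
            perm = rng.permutation(all_curves.shape[0])
            parts = np.split(all_curves[perm], edges)
            v_null[b] = fanova_statistic(dict(zip(keys, parts)), fs.grid)
    else:
        raise ValueError("method must be 'bootstrap' or 'permutation'")
    p = (1 + int((v_null >= v_obs).sum())) / (1 + B)
    return TestResult("functional-anova", v_obs, p, B, seed, groups=keys)


def _dcov_parts(curves: np.ndarray, grid: np.ndarray) -> np.ndarray:
    from .depth import l2_distance_matrix

    d = l2_distance_matrix(curves, grid)
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def functional_correlation_test(fsX: FunctionalSample, fsY: FunctionalSample,
                                n_perm: int = 999,
                                seed: int | None = None) -> TestResult:
    """Distance-covariance permutation test of dependence between curve sets.

    Curves must belong to the same individuals in the same order.  The
    statistic is the squared sample distance covariance of the two sets of
    curves under the L2 metric; the null is obtained by permuting which
    Y-curve is paired with which X-curve.
    """
    if list(fsX.ids) != list(fsY.ids):
        raise ValueError("curve sets must share individuals in the same order")
    n = fsX.n
    if n < 4:
        raise ValueError("need at least 4 paired curves")
    A = _dcov_parts(fsX.curves, fsX.grid)
    Bm = _dcov_parts(fsY.curves, fsY.grid)
    stat = float((A * Bm).mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if float((A * Bm[np.ix_(p, p)]).mean()) >= stat:
            count += 1
    pval = (1 + count) / (1 + n_perm)
    return TestResult("functional-dcov", stat, pval, n_perm, seed,
                      groups=["X", "Y"])


def compare_groups_report(enriched: pd.DataFrame, criteria=("L", "TFW"),
                          variables=None, grid_size: int = 101,
                          B: int = 500, seed: int | None = None,
                          with_bands: bool = False):
    """Functional-ANOVA comparison of fast vs slow growers, per criterion.

    For each split criterion (final-L and final-TFW median) and each
    variable, smooths the per-individual trajectories, runs :func:`fanova`
    between fast and slow groups and emits one tidy row.  Variables with too
    few usable curves per group yield a row marked not computed with the
    reason.

    Returns ``(report, bands)`` where ``bands`` maps
    (criterion, variable, group) -> (grid, mean, lower, upper) when
    ``with_bands`` is set (else an empty dict).
    """
    variables = list(variables) if variables is not None else list(REPORT_VARIABLES)
    rng = np.random.default_rng(seed)
    rows, bands = [], {}
    t_end = enriched["t"].max()
    for criterion in criteria:
        finals = (
            enriched[enriched["t"] == t_end]
            .set_index("individual_id")[criterion]
        )
        labels, excluded = classify_growers(finals, criterion)
        group_of = {l.individual_id: l.label for l in labels}
        for var in variables:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            trajs = trajectories_from_frame(
                enriched[enriched["individual_id"].isin(group_of)], var
            )
            try:
                fs, skipped = build_functional_sample(trajs, grid_size=grid_size)
                res = fanova(fs, labels, B=B, seed=sub_seed)
                rows.append({
                    "criterion": criterion, "variable": var,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "B": B, "seed": sub_seed,
                    "n_fast": sum(1 for i in fs.ids if group_of.get(i) == "fast"),
                    "n_slow": sum(1 for i in fs.ids if group_of.get(i) == "slow"),
                    "note": f"{len(skipped)} trajectories skipped" if skipped else "",
                })
                if with_bands:
                    for grp in ("fast", "slow"):
                        sub = fs.subset([i for i in fs.ids if group_of[i] == grp])
                        lo, hi = bootstrap_band(sub, B=max(B, 200), seed=sub_seed)
                        bands[(criterion, var, grp)] = (
                            fs.grid, functional_mean(sub), lo, hi
                        )
            except ValueError as exc:
                rows.append({
                    "criterion": criterion, "variable": var,
                    "statistic": np.nan, "p_value": np.nan, "B": B,
                    "seed": sub_seed, "n_fast": np.nan, "n_slow": np.nan,
                    "note": f"not computed: {exc}",
                })
    return pd.DataFrame(rows), bands
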