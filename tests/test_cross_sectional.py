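"""Plug-in KDE, rank ANOVA, Tukey-HSD and the dispersion permutation test."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from musselfda.cross_sectional import (
    PluginKDE,
    dispersion_test,
    kde_plugin,
    kruskal_wallis,
    plugin_bandwidth,
    tukey_hsd_on_ranks,
)


def brute_kruskal(groups):
    """Mid-rank H with tie correction, assembled from first principles."""
    pooled = np.concatenate(groups)
    order = pooled.argsort(kind="stable")
    ranks = np.empty_like(pooled)
    sorted_vals = pooled[order]
    r = np.arange(1, len(pooled) + 1, dtype=float)
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        r[i:j] = r[i:j].mean()
        i = j
    ranks[order] = r
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        rg = ranks[start:start + len(g)]
        h += rg.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


@pytest.mark.parametrize("groups,expected_h", [
    (([1.0, 2.0], [3.0, 4.0]), 2.4),
    (([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]), 27.0 / 7.0),
])
def test_kruskal_closed_form(groups, expected_h):
    res = kruskal_wallis(*groups)
    assert res.statistic == pytest.approx(expected_h, rel=1e-10)
    assert res.statistic == pytest.approx(brute_kruskal(groups), rel=1e-10)


def test_kruskal_identical_groups():
    res = kruskal_wallis([2.0, 2.0, 2.0], [2.0, 2.0])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_monotone_transform_invariant(rng):
    a, b, c = rng.normal(size=(3, 15))
    h1 = kruskal_wallis(a, b, c).statistic
    h2 = kruskal_wallis(np.exp(a), np.exp(b), np.exp(c)).statistic
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_tukey_on_ranks_behaviour(rng):
    same = rng.normal(size=(3, 20))
    res = tukey_hsd_on_ranks(*same)
    assert (res["p_value"] > 0.2).all()
    # two separated groups, one overlapping the first
    a = rng.normal(0, 1, 20)
    b = rng.normal(12, 1, 20)
    c = rng.normal(0.3, 1, 20)
    res = tukey_hsd_on_ranks(a, b, c, labels=["a", "b", "c"])
    res = res.set_index(["group_1", "group_2"])
    assert res.loc[("a", "b"), "p_value"] < 0.05
    assert res.loc[("b", "c"), "p_value"] < 0.05
    assert res.loc[("a", "c"), "p_value"] > 0.05
    # symmetry in group order
    assert res.loc[("a", "b"), "p_value"] == res.loc[("b", "a"), "p_value"]


def test_tukey_excludes_singletons(rng):
    with pytest.warns(UserWarning, match="n < 2"):
        res = tukey_hsd_on_ranks(rng.normal(size=10), rng.normal(size=10),
                                 [1.0])
    assert set(res["group_1"]) == {0, 1}


def test_plugin_kde_normalized_and_positive(rng):
    x = rng.normal(3.0, 2.0, 200)
    kde = PluginKDE().fit(x)
    assert (kde.density_ >= 0).all()
    assert np.trapezoid(kde.density_, kde.grid_) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError):
        kde_plugin(np.full(20, 1.0))
    with pytest.raises(ValueError):
        kde_plugin([1.0, 2.0])


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R oracle not available")
def test_plugin_bandwidth_matches_r_dpi_oracle(rng):
    """Two-stage direct plug-in agrees with R's bw.SJ(method='dpi')."""
    for loc in (0.0, 5.0):
        x = rng.normal(loc, 1.5, 200)
        h = plugin_bandwidth(x)
        with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as f:
            f.write("\n".join(f"{v:.17g}" for v in x))
            path = f.name
        try:
            out = subprocess.run(
                ["Rscript", "-e",
                 f'x<-scan("{path}",quiet=TRUE); cat(bw.SJ(x, method="dpi"))'],
                capture_output=True, text=True, timeout=120)
        finally:
            Path(path).unlink()
        h_r = float(out.stdout)
        assert abs(h / h_r - 1.0) < 0.25


def test_plugin_bandwidth_near_amise_for_normal(rng):
    """For N(0,1) data the plug-in lands near the known optimal rate value."""
    n = 400
    x = rng.standard_normal(n)
    h_ref = (4.0 / (3.0 * n)) ** 0.2 * x.std(ddof=1)  # normal-reference h
    assert abs(plugin_bandwidth(x) / h_ref - 1.0) < 0.25


def test_dispersion_detects_spread_difference(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(0, 5, 20)
    res = dispersion_test(np.concatenate([a, b]),
                          np.repeat(["a", "b"], 20), n_perm=399, seed=0)
    assert res.p_value < 0.01


def test_dispersion_location_shift_invariant(rng):
    vals = rng.standard_normal(60)
    g = np.repeat([0, 1, 2], 20)
    r1 = dispersion_test(vals, g, n_perm=199, seed=3)
    shifted = vals + g * 100.0  # group-specific constants
    r2 = dispersion_test(shifted, g, n_perm=199, seed=3)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
    assert r1.p_value == r2.p_value


def test_dispersion_constant_groups_p_one():
    vals = np.array([1.0] * 5 + [9.0] * 5)
    res = dispersion_test(vals, np.repeat([0, 1], 5), n_perm=199, seed=0)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_dispersion_reproducible_and_posthoc(rng):
    vals = rng.standard_normal(45)
    g = np.repeat([0, 1, 2], 15)
    r1 = dispersion_test(vals, g, n_perm=299, seed=11, post_hoc=True)
    r2 = dispersion_test(vals, g, n_perm=299, seed=11)
    assert r1.p_value == r2.p_value
    assert 1 / 300 <= r1.p_value <= 1.0
    assert set(r1.details["group_1"]) == {0, 1, 2}


def test_dispersion_multivariate_matches_univariate_on_1d(rng):
    vals = rng.standard_normal(30)
    g = np.repeat([0, 1], 15)
    r1 = dispersion_test(vals, g, n_perm=99, seed=1)
    r2 = dispersion_test(vals[:, None], g, n_perm=99, seed=1)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)


def test_dispersion_agrees_with_f_oneway_on_distances(rng):
    """The observed statistic is the plain ANOVA F on centroid distances."""
    vals = rng.normal(0, [1, 3], size=(20, 2)).ravel(order="F")
    g = np.repeat([0, 1], 20)
    z = [np.abs(vals[g == k] - vals[g == k].mean()) for k in (0, 1)]
    f_ref = stats.f_oneway(*z).statistic
    res = dispersion_test(vals, g, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(f_ref, rel=1e-10)
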