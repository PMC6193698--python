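"""Synthetic cohort generator: design shape, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from musselfda.energy import EnergyCoefficients, derive_all
from musselfda.simulate import CohortConfig, degrade, generate_cohort, plant_outliers


def test_default_design_shape(default_cohort):
    meas, diet, truth = default_cohort
    assert len(meas) == 48 * 6
    assert meas["individual_id"].nunique() == 48
    assert meas.groupby("tank_id")["individual_id"].nunique().tolist() == [16] * 3
    assert len(diet) == 3 * 6
    assert diet["POM"].between(0.673, 0.734).all()
    assert np.allclose(diet["TPM"], diet["PIM"] + diet["POM"])
    t0 = meas[meas["t"] == 0]
    assert t0["L"].between(18.5, 22.5).all()
    assert t0["TFW"].mean() == pytest.approx(0.66, abs=0.05)


def test_same_seed_identical_different_seed_not():
    a = generate_cohort(CohortConfig(seed=3))[0]
    b = generate_cohort(CohortConfig(seed=3))[0]
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(CohortConfig(seed=4))[0]
    assert not a["L"].equals(c["L"])


def test_degenerate_limit_no_variability():
    cfg = CohortConfig(
        seed=0, quality_sd=0.0,
        noise_sd={"CR": 0, "AE": 0, "VO2": 0, "VNH4": 0, "L": 0, "TFW": 0},
        L0_sd=1e-6, TFW0_sd=1e-6,
    )
    meas, diet, truth = generate_cohort(cfg)
    finals = meas[meas["t"] == 150].groupby("tank_id")
    # within a tank (same diet) all individuals are identical
    assert (finals["L"].std(ddof=0) < 1e-9).all()
    assert (finals["TFW"].std(ddof=0) < 1e-6).all()


def test_quality_drives_final_size(default_cohort):
    meas, _, truth = default_cohort
    finals = meas[meas["t"] == 150].set_index("individual_id")["TFW"]
    q = truth.set_index("individual_id")["quality"]
    r = np.corrcoef(q[finals.index], finals)[0, 1]
    assert r > 0.5


def test_size_dispersion_increases_across_samplings(default_cohort):
    meas, _, _ = default_cohort
    sds = meas.groupby("t")["TFW"].std()
    assert sds.is_monotonic_increasing
    l_sds = meas.groupby("t")["L"].std()
    assert l_sds.iloc[-1] > l_sds.iloc[0]


def test_generator_consistent_with_energy_budget(default_cohort):
    """derive_all on generated raw rates reproduces the internal SFG."""
    meas, diet, truth = default_cohort
    enriched, report = derive_all(meas, diet, EnergyCoefficients())
    assert len(report) == 0
    # recompute from raw columns: identity holds bitwise
    pom = enriched.merge(diet[["tank_id", "t", "POM"]], on=["tank_id", "t"])
    coeff = EnergyCoefficients()
    expect = coeff.q_POM * (pom["AE"] * (pom["CR"] * pom["POM"])) - (
        coeff.q_O2 * pom["VO2"] + coeff.q_NH4 * pom["VNH4"])
    assert np.array_equal(pom["SFG"].to_numpy(), expect.to_numpy())


def test_plant_outliers_rules(default_cohort):
    meas, _, _ = default_cohort
    same, planted = plant_outliers(meas, {})
    pd.testing.assert_frame_equal(same, meas)
    shifted, planted = plant_outliers(meas, {"M7": 10.0}, variable="L")
    assert planted == ["M7"]
    sd = meas["L"].std(ddof=1)
    delta = (shifted[shifted.individual_id == "M7"]["L"].to_numpy()
             - meas[meas.individual_id == "M7"]["L"].to_numpy())
    assert np.allclose(delta, 10 * sd)
    # TFW untouched, bit for bit
    assert shifted["TFW"].equals(meas["TFW"])
    with pytest.raises(ValueError, match="unknown"):
        plant_outliers(meas, {"nope": 1.0})


def test_degrade_missingness(default_cohort):
    meas, _, _ = default_cohort
    assert degrade(meas, 0.0, seed=0).equals(meas)
    rate = 0.1
    out = degrade(meas, rate, seed=1)
    n_cells = len(meas) * 4
    n_missing = int(out[["CR", "AE", "VO2", "VNH4"]].isna().sum().sum())
    lo, hi = stats.binom.interval(0.99, n_cells, rate)
    assert lo <= n_missing <= hi
    # endpoint sizes never go missing
    ends = out[(out["t"] == 0) | (out["t"] == 150)]
    assert ends["L"].notna().all() and ends["TFW"].notna().all()
    with pytest.raises(ValueError):
        degrade(meas, 0.5)


def test_degraded_cohort_still_smoothable(default_cohort):
    """Missing rate cells flow through derive_all and smoothing untouched."""
    from musselfda.smoothing import build_functional_sample, trajectories_from_frame

    meas, diet, _ = default_cohort
    degraded = degrade(meas, 0.15, seed=3)
    enriched, _ = derive_all(degraded, diet)
    assert enriched["SFG"].isna().sum() > 0
    fs, skipped = build_functional_sample(
        trajectories_from_frame(enriched, "SFG"), grid_size=31)
    assert fs.n + len(skipped) == 48
    assert np.isfinite(fs.curves).all()


def test_planted_cohort_outlier_recovered_by_detector(default_cohort):
    """A +10 pooled-sd shell-length shift survives smoothing and is flagged."""
    from musselfda.depth import trimmed_mode_outliers
    from musselfda.smoothing import build_functional_sample, trajectories_from_frame

    meas, _, _ = default_cohort
    shifted, _ = plant_outliers(meas, {"M5": 10.0}, variable="L")
    fs, _ = build_functional_sample(
        trajectories_from_frame(shifted, "L"), grid_size=51)
    res = trimmed_mode_outliers(fs, B=200, seed=0)
    assert "M5" in res.outlier_ids


def test_config_validation():
    with pytest.raises(ValueError, match="divide"):
        CohortConfig(n_individuals=10, n_tanks=3)
    with pytest.raises(ValueError, match="negative sizes"):
        CohortConfig(L0_mean=1.0, L0_sd=2.0)
    with pytest.raises(ValueError, match="increasing"):
        CohortConfig(samplings=(0.0, 60.0, 30.0))
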