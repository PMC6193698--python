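"""Energy-budget arithmetic, QC rules, and the diet join."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from musselfda.energy import (
    EnergyCoefficients,
    absorption_rate,
    clearance_rate,
    conover_ae,
    derive_all,
    metabolic_cost,
    organic_ingestion_rate,
    scope_for_growth,
)


@pytest.mark.parametrize("flow,c_in,c_out,expected", [
    (10, 10000, 10000, 0.0),      # no depletion
    (10, 10000, 0, 10.0),         # full depletion: CR equals the flow
    (12, 10000, 7500, 3.0),       # flow * 2500/10000
])
def test_clearance_rate_flow_through(flow, c_in, c_out, expected):
    assert clearance_rate(flow, c_in, c_out) == pytest.approx(expected, abs=1e-12)


def test_clearance_rate_qc():
    with pytest.raises(ValueError):
        clearance_rate(10, 0, 0)
    with pytest.warns(UserWarning):
        assert clearance_rate(10, 1000, 1100) == 0.0
    with pytest.raises(ValueError):
        clearance_rate(10, 1000, 1100, on_excess="raise")


@pytest.mark.parametrize("cr,pom,expected", [
    (0.0, 0.7, 0.0),
    (2.0, 0.673, 1.346),   # lower bound of the observed diet POM range
    (1.5, 0.734, 1.101),   # upper bound
])
def test_organic_ingestion_rate(cr, pom, expected):
    assert organic_ingestion_rate(cr, pom) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("F,E,expected", [
    (0.5, 0.5, 0.0),             # feces as organic as food
    (0.5, 0.0, 1.0),             # fully inorganic feces
    (0.7, 0.4, 0.3 / 0.42),      # (0.7-0.4)/((1-0.4)*0.7)
])
def test_conover_ratio(F, E, expected):
    assert conover_ae(F, E) == pytest.approx(expected, rel=1e-12)


def test_conover_domain_and_negative_values():
    for F, E in [(0.0, 0.1), (1.0, 0.1), (0.5, 1.0), (0.5, -0.1)]:
        with pytest.raises(ValueError):
            conover_ae(F, E)
    assert conover_ae(0.4, 0.6) < 0  # retained, not truncated


@pytest.mark.parametrize("ae,oir,expected", [
    (1.0, 1.2, 1.2), (0.0, 1.2, 0.0), (0.6, 1.346, 0.8076),
])
def test_absorption_rate(ae, oir, expected):
    assert absorption_rate(ae, oir) == pytest.approx(expected, abs=1e-12)


def test_metabolic_cost_and_sfg():
    coeff = EnergyCoefficients()
    assert metabolic_cost(0, 0) == 0.0
    assert metabolic_cost(0.1, 0) == pytest.approx(2.033)
    m = metabolic_cost(0.1, 10)
    assert m == pytest.approx(20.33 * 0.1 + 0.02483 * 10)
    assert scope_for_growth(0.0, 2.0) == -2.0
    assert scope_for_growth(0.8076, m) == pytest.approx(17.9 * 0.8076 - m)
    # missing inputs propagate
    assert np.isnan(metabolic_cost(np.nan, 1.0))
    assert np.isnan(scope_for_growth(np.nan, 1.0))


def test_energy_coefficients_must_be_positive():
    with pytest.raises(ValueError):
        EnergyCoefficients(q_O2=-1)


@given(
    cr=st.floats(0, 10), ae=st.floats(0, 1), pom=st.floats(0, 2),
    vo2=st.floats(0, 5), vnh4=st.floats(0, 100),
)
def test_budget_conservation_property(cr, ae, pom, vo2, vnh4):
    """SFG + M equals the absorbed energy q_POM*AE*CR*POM identically."""
    coeff = EnergyCoefficients()
    oir = organic_ingestion_rate(cr, pom)
    ar = absorption_rate(ae, oir)
    m = metabolic_cost(vo2, vnh4, coeff)
    sfg = scope_for_growth(ar, m, coeff)
    absorbed = coeff.q_POM * ae * cr * pom
    assert sfg + m == pytest.approx(absorbed, rel=1e-12, abs=1e-12)
    assert ar <= oir + 1e-15


def _toy_tables():
    records = pd.DataFrame({
        "individual_id": ["a", "b", "c"],
        "tank_id": ["T1", "T1", "T2"],
        "t": [0.0, 0.0, 0.0],
        "L": [20.0, 21.0, 20.5],
        "TFW": [0.6, 0.7, 0.65],
        "CR": [2.0, 1.5, np.nan],
        "AE": [0.5, np.nan, 0.6],
        "VO2": [0.2, 0.2, 0.2],
        "VNH4": [4.0, 4.0, 4.0],
    })
    diet = pd.DataFrame({
        "tank_id": ["T1", "T2"], "t": [1.0, 1.0],
        "TPM": [1.0, 1.0], "PIM": [0.3, 0.3], "POM": [0.7, 0.7],
    })
    return records, diet


def test_derive_all_completeness_and_propagation():
    records, diet = _toy_tables()
    enriched, report = derive_all(records, diet)
    assert len(report) == 0 and len(enriched) == 3
    a = enriched.set_index("individual_id")
    # complete record: all four derived fields
    assert np.isfinite(
        a.loc["a", ["OIR", "AR", "M", "SFG"]].astype(float)).all()
    # missing AE: OIR present, AR/SFG missing
    assert np.isfinite(a.loc["b", "OIR"])
    assert np.isnan(a.loc["b", "AR"]) and np.isnan(a.loc["b", "SFG"])
    # missing CR: OIR missing too
    assert np.isnan(a.loc["c", "OIR"])


def test_derive_all_empty_and_unmatched():
    records, diet = _toy_tables()
    empty, report = derive_all(records.iloc[:0], diet)
    assert len(empty) == 0 and len(report) == 0
    far_diet = diet.assign(t=[30.0, 30.0])  # outside the +/-3 d window
    enriched, report = derive_all(records, far_diet)
    assert len(enriched) == 3           # rows never dropped
    assert len(report) == 3
    assert enriched["OIR"].isna().all()


def test_derive_all_row_order_invariance():
    records, diet = _toy_tables()
    fwd, _ = derive_all(records, diet)
    rev, _ = derive_all(records.iloc[::-1], diet)
    merged = fwd.set_index("individual_id")[["OIR", "M", "SFG"]]
    merged_rev = rev.set_index("individual_id")[["OIR", "M", "SFG"]]
    pd.testing.assert_frame_equal(merged.sort_index(), merged_rev.sort_index())


def test_sfg_monotone_in_inputs():
    coeff = EnergyCoefficients()

    def sfg(cr, ae, pom, vo2, vnh4):
        return scope_for_growth(
            absorption_rate(ae, organic_ingestion_rate(cr, pom)),
            metabolic_cost(vo2, vnh4, coeff), coeff)

    base = sfg(2, 0.5, 0.7, 0.2, 4)
    assert sfg(2.5, 0.5, 0.7, 0.2, 4) > base
    assert sfg(2, 0.6, 0.7, 0.2, 4) > base
    assert sfg(2, 0.5, 0.73, 0.2, 4) > base
    assert sfg(2, 0.5, 0.7, 0.3, 4) < base
    assert sfg(2, 0.5, 0.7, 0.2, 9) < base
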