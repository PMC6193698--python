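"""Scope-for-growth energy budget for suspension-feeding bivalves.

Derives feeding, digestion and metabolic quantities from raw per-individual
measurements and closes the energy balance

    SFG = q_POM * AR - M,      M = q_O2 * VO2 + q_NH4 * VNH4

where AR = AE * OIR and OIR = CR * POM.  SFG (scope for growth, J/h) is the
energy left for somatic and gametogenic growth after metabolic maintenance.

All rate functions are vectorised over numpy arrays and propagate NaN as
"missing"; validation raises on physically impossible inputs rather than
silently clamping, except where a documented QC rule applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnergyCoefficients",
    "clearance_rate",
    "organic_ingestion_rate",
    "conover_ae",
    "absorption_rate",
    "metabolic_cost",
    "scope_for_growth",
    "derive_all",
]

#: canonical column order of a measurements table
MEASUREMENT_COLUMNS = [
    "individual_id", "tank_id", "t", "L", "TFW", "CR", "AE", "VO2", "VNH4",
]
DIET_COLUMNS = ["tank_id", "t", "TPM", "PIM", "POM"]


@dataclass(frozen=True)
class EnergyCoefficients:
    """Energy conversion constants closing the budget in J/h.

    Defaults are the oxycaloric / ammonia-N / organic-matter coefficients in
    routine use in the mussel scope-for-growth literature; all are
    overridable (e.g. from a run config) since reported SFG magnitudes depend
    directly on them.

    Attributes
    ----------
    q_O2 : J per ml O2 respired (oxycaloric coefficient).
    q_NH4 : J per microgram NH4-N excreted.
    q_POM : J per mg organic matter absorbed.
    """

    q_O2: float = 20.33
    q_NH4: float = 0.02483
    q_POM: float = 17.9

    def __post_init__(self) -> None:
        if not (self.q_O2 > 0 and self.q_NH4 > 0 and self.q_POM > 0):
            raise ValueError("energy coefficients must be strictly positive")


def clearance_rate(flow, c_in, c_out, *, on_excess="clamp"):
    """Flow-through clearance rate CR = flow * (c_in - c_out) / c_in (l/h).

    ``c_out > c_in`` (impossible particle production, typically counter
    noise) yields CR = 0 with a warning when ``on_excess='clamp'``, or a
    ``ValueError`` when ``on_excess='raise'``.
    """
    flow = np.asarray(flow, dtype=float)
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if np.any(flow <= 0):
        raise ValueError("flow must be positive")
    if np.any(c_in <= 0):
        raise ValueError("inflow concentration must be positive")
    if np.any(c_out < 0):
        raise ValueError("outflow concentration must be non-negative")
    excess = c_out > c_in
    if np.any(excess):
        if on_excess == "raise":
            raise ValueError("c_out exceeds c_in")
        warnings.warn(
            "c_out > c_in in clearance measurement; CR set to 0",
            UserWarning, stacklevel=2,
        )
    cr = flow * (c_in - c_out) / c_in
    cr = np.where(excess, 0.0, cr)
    return cr if cr.ndim else float(cr)


def organic_ingestion_rate(CR, POM):
    """Organic ingestion rate OIR = CR * POM (mg/h)."""
    CR = np.asarray(CR, dtype=float)
    POM = np.asarray(POM, dtype=float)
    if np.any(CR < 0) or np.any(POM < 0):
        raise ValueError("CR and POM must be non-negative")
    out = CR * POM
    return out if out.ndim else float(out)


def conover_ae(F, E):
    """Conover ash-ratio absorption efficiency AE = (F - E) / ((1 - E) * F).

    ``F`` and ``E`` are the organic fractions of the food and of the feces.
    AE < 0 (feces more organic than food) is physically suspect but returned
    as-is so that downstream QC can flag rather than bias the record.
    """
    F = np.asarray(F, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any((F <= 0) | (F >= 1)):
        raise ValueError("food organic fraction F must lie in (0, 1)")
    if np.any((E < 0) | (E >= 1)):
        raise ValueError("feces organic fraction E must lie in [0, 1)")
    ae = (F - E) / ((1.0 - E) * F)
    return ae if ae.ndim else float(ae)


def absorption_rate(AE, OIR):
    """Absorption rate AR = AE * OIR (mg/h)."""
    AE = np.asarray(AE, dtype=float)
    OIR = np.asarray(OIR, dtype=float)
    if np.any(OIR < 0):
        raise ValueError("OIR must be non-negative")
    out = AE * OIR
    return out if out.ndim else float(out)


def metabolic_cost(VO2, VNH4, coeff: EnergyCoefficients | None = None):
    """Metabolic cost M = q_O2*VO2 + q_NH4*VNH4 (J/h); NaN inputs propagate."""
    coeff = coeff or EnergyCoefficients()
    VO2 = np.asarray(VO2, dtype=float)
    VNH4 = np.asarray(VNH4, dtype=float)
    if np.any(VO2 < 0) or np.any(VNH4 < 0):
        raise ValueError("respiration and excretion rates must be non-negative")
    out = coeff.q_O2 * VO2 + coeff.q_NH4 * VNH4
    return out if out.ndim else float(out)


def scope_for_growth(AR, M, coeff: EnergyCoefficients | None = None):
    """Scope for growth SFG = q_POM * AR - M (J/h); may be negative."""
    coeff = coeff or EnergyCoefficients()
    AR = np.asarray(AR, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("metabolic cost must be non-negative")
    out = coeff.q_POM * AR - M
    return out if out.ndim else float(out)


def _validate_measurements(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"measurements table missing columns: {missing}")
    return records


def derive_all(
    records: pd.DataFrame,
    diet: pd.DataFrame,
    coeff: EnergyCoefficients | None = None,
    *,
    join_window: float = 3.0,
):
    """Join each measurement to its tank's diet and compute all derived rates.

    Parameters
    ----------
    records : measurements table with :data:`MEASUREMENT_COLUMNS`.
    diet : diet table with :data:`DIET_COLUMNS`.
    coeff : energy conversion constants (defaults used if None).
    join_window : maximum |t_record - t_diet| (days) for the per-tank
        nearest-in-time diet match.

    Returns
    -------
    enriched : copy of ``records`` with OIR, AR, M, SFG and ``qc_flags``
        columns appended; missing inputs propagate to missing outputs.
    join_report : one row per record that found no diet match within the
        window (records are kept with missing derived values, never dropped).
    """
    coeff = coeff or EnergyCoefficients()
    records = _validate_measurements(records)
    out = records.copy().reset_index(drop=True)
    n = len(out)
    pom = np.full(n, np.nan)
    unmatched = []
    if n:
        diet = diet.sort_values("t")
        for tank, idx in out.groupby("tank_id").groups.items():
            sub = diet[diet["tank_id"] == tank]
            for i in idx:
                t = out.at[i, "t"]
                if len(sub) == 0:
                    unmatched.append((i, tank, t, "no diet rows for tank"))
                    continue
                gap = np.abs(sub["t"].to_numpy(dtype=float) - float(t))
                j = int(np.argmin(gap))
                if gap[j] <= join_window:
                    pom[i] = sub["POM"].to_numpy(dtype=float)[j]
                else:
                    unmatched.append(
                        (i, tank, t, f"nearest diet sampling {gap[j]:.1f} d away")
                    )

    cr = out["CR"].to_numpy(dtype=float)
    ae = out["AE"].to_numpy(dtype=float)
    vo2 = out["VO2"].to_numpy(dtype=float)
    vnh4 = out["VNH4"].to_numpy(dtype=float)

    oir = cr * pom
    ar = ae * oir
    m = coeff.q_O2 * vo2 + coeff.q_NH4 * vnh4
    sfg = coeff.q_POM * ar - m

    flags = np.asarray(
        [";".join(f) if f else "" for f in
         (["negative_AE"] if a < 0 else [] for a in np.nan_to_num(ae, nan=0.0))],
        dtype=object,
    )
    out["OIR"] = oir
    out["AR"] = ar
    out["M"] = m
    out["SFG"] = sfg
    out["qc_flags"] = flags
    report = pd.DataFrame(
        unmatched, columns=["row", "tank_id", "t", "reason"]
    )
    return out, report
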