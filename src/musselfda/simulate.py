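"""Synthetic longitudinal mussel cohorts with a planted physiological basis
for growth variability.

The generator emulates the study design the analysis modules expect: 48
juvenile mussels, 16 per flow-through tank (3 tanks), measured at 6 monthly
samplings over ~150 days, starting even-sized (shell length ~20-21 mm,
total fresh weight 0.66 g, sd 0.089) under a shared diet whose particulate
organic matter is constant per tank and experiment within 0.673-0.734 mg/l.

Each individual carries a latent quality factor q_i ~ N(0, quality_sd^2)
that raises its feeding (CR) and digestion (AE) and, by default, lowers its
metabolic rates — the energy-acquisition / metabolic-efficiency reading of
growth variability.  Sizes grow mechanistically: the scope for growth
implied by the recorded (noisy) rates is integrated between samplings, so
between-individual size dispersion increases over time and fast growers are
fast *because* of their physiology.  Rate magnitudes are order-of-magnitude
placeholders targeting statistical structure, not calibrated physiology.

Raw rates are written with measurement noise BEFORE the internal SFG is
computed, so :func:`musselfda.energy.derive_all` recovers the generator's
ground-truth SFG exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyCoefficients

__all__ = ["CohortConfig", "generate_cohort", "plant_outliers", "degrade"]


@dataclass
class CohortConfig:
    """Design constants and effect sizes of a synthetic cohort.

    Loadings are multiplicative per unit of latent quality (a loading of
    0.2 means +20% at q = +1); noise sds are relative for rates except AE,
    whose noise is additive on the fraction scale.  ``dispersion_growth``
    inflates between-individual rate noise by that factor per sampling.
    """

    n_individuals: int = 48
    n_tanks: int = 3
    samplings: tuple = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    L0_mean: float = 20.5
    L0_sd: float = 0.5
    TFW0_mean: float = 0.66
    TFW0_sd: float = 0.089
    POM_range: tuple = (0.673, 0.734)
    organic_fraction: tuple = (0.72, 0.75)  # POM/TPM range of the diet
    quality_sd: float = 1.0
    loadings: dict = field(default_factory=lambda: {
        "CR": 0.20, "AE": 0.10, "VO2": -0.08, "VNH4": -0.08,
    })
    noise_sd: dict = field(default_factory=lambda: {
        "CR": 0.12, "AE": 0.04, "VO2": 0.12, "VNH4": 0.15,
        "L": 0.05, "TFW": 0.005,
    })
    baselines: dict = field(default_factory=lambda: {
        "CR": 1.5, "AE": 0.55, "VO2": 0.25, "VNH4": 4.0,
    })
    allometry: dict = field(default_factory=lambda: {
        "CR": 0.4, "AE": 0.0, "VO2": 0.7, "VNH4": 0.7,
    })
    dispersion_growth: float = 1.15
    growth_gain: float = 3.5e-5  # g fresh weight per J of positive SFG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals % self.n_tanks:
            raise ValueError("n_individuals must divide evenly across tanks")
        if any(s < 0 for s in self.noise_sd.values()) or self.quality_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if np.any(np.diff(self.samplings) <= 0):
            raise ValueError("samplings must be strictly increasing")
        if self.L0_mean - 4 * self.L0_sd <= 0 or self.TFW0_mean - 4 * self.TFW0_sd <= 0:
            raise ValueError("initial size distribution implies negative sizes")


def _rate(cfg: CohortConfig, var: str, q, rel_size, s: int, rng) -> np.ndarray:
    base = cfg.baselines[var] * rel_size ** cfg.allometry[var]
    level = base * (1.0 + cfg.loadings[var] * q)
    scale = cfg.dispersion_growth**s
    if var == "AE":
        noisy = level + rng.normal(0, cfg.noise_sd[var] * scale, size=q.shape)
        return np.clip(noisy, 0.0, 1.0)
    noisy = level * (1.0 + rng.normal(0, cfg.noise_sd[var] * scale, size=q.shape))
    return np.maximum(noisy, 0.0)


def generate_cohort(cfg: CohortConfig | None = None,
                    coeff: EnergyCoefficients | None = None):
    """Simulate one cohort.

    Returns
    -------
    measurements : long table, one row per individual x sampling, with the
        raw columns consumed by :func:`musselfda.energy.derive_all`
        (L rounded to 0.1 mm, TFW to 1 mg — caliper/balance precision).
    diet : per tank x sampling TPM/PIM/POM table.
    truth : per-individual ground truth (quality q_i, its sign group, and
        the generator's cumulative SFG) — for validation only, never an
        input to the analysis modules.
    """
    cfg = cfg or CohortConfig()
    coeff = coeff or EnergyCoefficients()
    rng = np.random.default_rng(cfg.seed)
    n, times = cfg.n_individuals, np.asarray(cfg.samplings, dtype=float)
    per_tank = n // cfg.n_tanks
    tanks = np.repeat([f"T{k+1}" for k in range(cfg.n_tanks)], per_tank)
    ids = [f"M{i+1}" for i in range(n)]

    q = rng.normal(0.0, cfg.quality_sd, size=n)
    L = rng.normal(cfg.L0_mean, cfg.L0_sd, size=n)
    TFW = rng.normal(cfg.TFW0_mean, cfg.TFW0_sd, size=n)
    L0, TFW0 = L.copy(), TFW.copy()

    # constant POM per tank x sampling, organic fraction in the diet's range
    pom = rng.uniform(*cfg.POM_range, size=(cfg.n_tanks, times.size))
    frac = rng.uniform(*cfg.organic_fraction, size=(cfg.n_tanks, times.size))
    tpm = pom / frac
    diet = pd.DataFrame({
        "tank_id": np.repeat([f"T{k+1}" for k in range(cfg.n_tanks)], times.size),
        "t": np.tile(times, cfg.n_tanks),
        "TPM": tpm.ravel(),
        "PIM": (tpm - pom).ravel(),
        "POM": pom.ravel(),
    })
    pom_of = {(r.tank_id, r.t): r.POM for r in diet.itertuples()}

    rows = []
    cum_sfg = np.zeros(n)
    for s, t in enumerate(times):
        rel = TFW / cfg.TFW0_mean
        cr = _rate(cfg, "CR", q, rel, s, rng)
        ae = _rate(cfg, "AE", q, rel, s, rng)
        vo2 = _rate(cfg, "VO2", q, rel, s, rng)
        vnh4 = _rate(cfg, "VNH4", q, rel, s, rng)
        pom_i = np.array([pom_of[(tk, t)] for tk in tanks])
        # associate exactly as energy.derive_all does, so recovery is bitwise
        sfg = coeff.q_POM * (ae * (cr * pom_i)) - (coeff.q_O2 * vo2 + coeff.q_NH4 * vnh4)

        L_meas = np.round(L + rng.normal(0, cfg.noise_sd["L"], n), 1)
        TFW_meas = np.round(TFW + rng.normal(0, cfg.noise_sd["TFW"], n), 3)
        rows.append(pd.DataFrame({
            "individual_id": ids, "tank_id": tanks, "t": t,
            "L": np.maximum(L_meas, 0.1), "TFW": np.maximum(TFW_meas, 1e-3),
            "CR": cr, "AE": ae, "VO2": vo2, "VNH4": vnh4,
        }))

        if s + 1 < times.size:
            dt_h = (times[s + 1] - t) * 24.0
            energy = np.maximum(sfg, 0.0) * dt_h
            cum_sfg += energy
            TFW = TFW + cfg.growth_gain * energy
            L = L0 * np.cbrt(TFW / TFW0)  # isometric shell-tissue scaling

    measurements = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "individual_id": ids, "tank_id": tanks, "quality": q,
        "true_group": np.where(q > 0, "fast", "slow"),
        "cumulative_sfg_J": cum_sfg,
    })
    return measurements, diet, truth


def plant_outliers(measurements: pd.DataFrame, shifts: dict,
                   variable: str = "L"):
    """Shift whole trajectories of chosen individuals by multiples of the
    pooled sd of ``variable``.

    ``shifts`` maps individual id -> shift in pooled-sd units.  Returns the
    modified copy and the ground-truth list of planted ids.
    """
    out = measurements.copy()
    known = set(out["individual_id"])
    unknown = set(shifts) - known
    if unknown:
        raise ValueError(f"unknown individual ids: {sorted(unknown)}")
    pooled_sd = float(out[variable].std(ddof=1))
    for iid, shift in shifts.items():
        m = out["individual_id"] == iid
        out.loc[m, variable] = out.loc[m, variable] + shift * pooled_sd
    return out, sorted(shifts)


RATE_COLUMNS = ["CR", "AE", "VO2", "VNH4"]


def degrade(measurements: pd.DataFrame, missing_rate: float,
            seed: int | None = None) -> pd.DataFrame:
    """Knock out rate cells at random to exercise missing-data handling.

    Each physiological rate cell goes missing independently with probability
    ``missing_rate``; size measurements at an individual's first and last
    sampling are never touched (the growth endpoints anchor the analysis).
    Rates of 0.3 or more would leave curves with fewer than the 3 points
    smoothing needs, and raise.
    """
    if not 0 <= missing_rate < 0.3:
        raise ValueError("missing_rate must lie in [0, 0.3)")
    out = measurements.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in RATE_COLUMNS:
        mask = rng.random(len(out)) < missing_rate
        out.loc[mask, col] = np.nan
    # middle size measurements may also drop out; endpoints never do
    t_first = out.groupby("individual_id")["t"].transform("min")
    t_last = out.groupby("individual_id")["t"].transform("max")
    protect = (out["t"] == t_first) | (out["t"] == t_last)
    for col in ("L", "TFW"):
        mask = (rng.random(len(out)) < missing_rate) & ~protect
        out.loc[mask, col] = np.nan
    return out
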