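"""End-to-end orchestration of the growth-variability analysis.

Stage order is fixed, mirroring how the analysis is meant to be read:

  derive rates -> smooth trajectories -> detect & exclude functional
  outliers -> cross-sectional homogeneity/dispersion tests -> even-start
  subsample -> median split -> functional ANOVA group report

A single master seed drives every stochastic stage through per-stage seeds
derived by stable hashing of the stage name, so the whole run is a pure
function of (input data, config, seed).  Failures halt with the stage name;
artifacts written so far are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_sectional import dispersion_test, kruskal_wallis, tukey_hsd_on_ranks
from .depth import trimmed_mode_outliers
from .energy import EnergyCoefficients, derive_all
from .groups import REPORT_VARIABLES, compare_groups_report, select_even_start
from .io import read_diet, read_measurements
from .simulate import CohortConfig, generate_cohort
from .smoothing import build_functional_sample, trajectories_from_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "validate_inputs", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the data themselves.

    Exactly one of ``measurements_path`` (+ ``diet_path``) or ``synthetic``
    must be provided.
    """

    measurements_path: str | None = None
    diet_path: str | None = None
    synthetic: CohortConfig | None = None
    coefficients: EnergyCoefficients = field(default_factory=EnergyCoefficients)
    grid_size: int = 101
    outlier_trim: float = 0.1
    outlier_B: int = 200
    outlier_alpha_cut: float = 0.01
    outlier_variables: tuple = ("L", "TFW")
    n_perm: int = 999
    B_fanova: int = 500
    criteria: tuple = ("L", "TFW")
    even_start_target: float = 21.0
    even_start_tolerance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.measurements_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "provide exactly one of input paths or a synthetic config"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "samplings" in syn:
                syn["samplings"] = tuple(syn["samplings"])
            raw["synthetic"] = CohortConfig(**syn)
        if "coefficients" in raw:
            raw["coefficients"] = EnergyCoefficients(**raw["coefficients"])
        for key in ("criteria", "outlier_variables"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_inputs(measurements: pd.DataFrame,
                    diet: pd.DataFrame) -> pd.DataFrame:
    """Schema/range/consistency checks; returns a violations table."""
    v = []

    def add(table, row, column, message):
        v.append({"table": table, "row": row, "column": column,
                  "message": message})

    ranges = {"L": (0, 300, False), "TFW": (0, 1000, False),
              "CR": (0, 50, True), "AE": (0, 1, True),
              "VO2": (0, 50, True), "VNH4": (0, 1e4, True)}
    for col, (lo, hi, inclusive) in ranges.items():
        x = measurements[col]
        bad = (x < lo) | (x > hi) if inclusive else (x <= lo) | (x > hi)
        for i in measurements.index[bad.fillna(False)]:
            add("measurements", int(i), col, f"value {x[i]} outside [{lo}, {hi}]")
    dup = measurements.duplicated(subset=["individual_id", "t"], keep=False)
    for i in measurements.index[dup]:
        add("measurements", int(i), "individual_id,t", "duplicate (id, t) row")
    for iid, g in measurements.groupby("individual_id"):
        if g["t"].isna().any():
            add("measurements", -1, "t", f"{iid}: missing sampling time")
    bal = (diet["TPM"] - diet["PIM"] - diet["POM"]).abs()
    for i in diet.index[bal > 1e-6 + 1e-6 * diet["TPM"].abs()]:
        add("diet", int(i), "TPM", "TPM != PIM + POM")
    for i in diet.index[(diet[["TPM", "PIM", "POM"]] < 0).any(axis=1)]:
        add("diet", int(i), "TPM/PIM/POM", "negative particulate load")
    return pd.DataFrame(v, columns=["table", "row", "column", "message"])


def _load(config: RunConfig):
    if config.synthetic is not None:
        meas, diet, truth = generate_cohort(config.synthetic,
                                            config.coefficients)
        return meas, diet, truth
    meas, origin = read_measurements(config.measurements_path)
    diet, _ = read_diet(config.diet_path, origin)
    return meas, diet, None


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written).

    Artifacts in ``out_dir``: enriched.csv, join_report.csv, curves.csv (+
    curves_meta.json), outliers.csv, tests.csv, group_report.csv,
    manifest.json and run.log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("musselfda")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "load"
    try:
        meas, diet, truth = _load(config)
        if truth is not None:
            truth.to_csv(out / "ground_truth.csv", index=False)
        violations = validate_inputs(meas, diet)
        if len(violations):
            logger.warning("%d input violations (see validation.csv)",
                           len(violations))
            violations.to_csv(out / "validation.csv", index=False)

        stage = "derive"
        enriched, join_report = derive_all(meas, diet, config.coefficients)
        enriched.to_csv(out / "enriched.csv", index=False)
        join_report.to_csv(out / "join_report.csv", index=False)

        stage = "smooth"
        samples, skip_all = {}, []
        for var in REPORT_VARIABLES:
            trajs = trajectories_from_frame(enriched, var)
            fs, skipped = build_functional_sample(trajs, config.grid_size)
            samples[var] = fs
            skip_all += [(var, *s) for s in skipped]
        frames = []
        for var, fs in samples.items():
            f = fs.to_frame()
            f.insert(0, "variable", var)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(out / "curves.csv",
                                                    index=False)
        meta = {var: {"grid": fs.grid.tolist(),
                      "bandwidths": fs.bandwidths.tolist()}
                for var, fs in samples.items()}
        meta["skipped"] = [list(map(str, s)) for s in skip_all]
        (out / "curves_meta.json").write_text(json.dumps(meta))

        stage = "outliers"
        flagged = []
        outlier_rows = []
        for var in config.outlier_variables:
            res = trimmed_mode_outliers(
                samples[var], trim=config.outlier_trim, B=config.outlier_B,
                alpha_cut=config.outlier_alpha_cut,
                seed=stage_seed(config.seed, f"outliers:{var}"),
            )
            flagged += res.outlier_ids
            df = res.to_frame(samples[var].ids)
            df.insert(0, "variable", var)
            outlier_rows.append(df)
        pd.concat(outlier_rows, ignore_index=True).to_csv(
            out / "outliers.csv", index=False)
        flagged = sorted(set(flagged))
        logger.info("excluding %d functional outliers: %s", len(flagged), flagged)
        kept = enriched[~enriched["individual_id"].isin(flagged)]

        stage = "cross_sectional"
        test_rows = []
        for var in REPORT_VARIABLES:
            by_t = [g[var].dropna().to_numpy()
                    for _, g in kept.groupby("t", sort=True)]
            by_t = [g for g in by_t if g.size >= 3]
            if len(by_t) < 2:
                continue
            kw = kruskal_wallis(*by_t)
            test_rows.append({"method": kw.method, "variable": var,
                              "statistic": kw.statistic, "p_value": kw.p_value,
                              "n_resamples": None, "seed": None})
            vals = kept[[var, "t"]].dropna()
            counts = vals.groupby("t")[var].transform("size")
            vals = vals[counts >= 3]
            disp = dispersion_test(
                vals[var].to_numpy(), vals["t"].to_numpy(),
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"dispersion:{var}"),
            )
            test_rows.append({"method": disp.method, "variable": var,
                              "statistic": disp.statistic,
                              "p_value": disp.p_value,
                              "n_resamples": disp.n_resamples,
                              "seed": disp.seed})
        pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)

        stage = "groups"
        even_ids = select_even_start(
            kept, "L", config.even_start_target, config.even_start_tolerance)
        logger.info("even-start subsample: %d individuals", len(even_ids))
        report, _ = compare_groups_report(
            kept[kept["individual_id"].isin(even_ids)],
            criteria=config.criteria, grid_size=config.grid_size,
            B=config.B_fanova, seed=stage_seed(config.seed, "fanova"),
        )
        report.to_csv(out / "group_report.csv", index=False)

        stage = "manifest"
        cfg_dict = config.to_dict()
        manifest = {
            "package_version": __version__,
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "master_seed": config.seed,
            "n_individuals": int(meas["individual_id"].nunique()),
            "n_records": int(len(meas)),
            "outliers_excluded": [str(f) for f in flagged],
            "even_start_n": len(even_ids),
            "n_input_violations": int(len(violations)),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
        return manifest
    except Exception as exc:
        logger.exception("pipeline halted at stage %r", stage)
        raise RuntimeError(f"pipeline halted at stage {stage!r}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
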