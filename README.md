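# musselfda

Functional data analysis of **individual growth variability** in
longitudinally sampled bivalves, built around the **scope-for-growth (SFG)
energy budget**.

## The problem

Even-aged, even-sized mussels reared under identical conditions diverge in
size over a few months. Whether that divergence is *driven* by individual
differences in physiology (feeding, digestion, metabolism) cannot be decided
from a single end-point measurement: by the time fast growers are visibly
larger, their rates differ simply because rates scale with body size.
Deciding causality requires repeated measurements of the same individuals
*while* the divergence is happening, and statistics that treat each
individual's trajectory as a single observation — a curve.

`musselfda` implements that workflow for cohorts monitored at monthly
samplings: shell length *L* (mm), total fresh weight *TFW* (g), clearance
rate *CR* (l/h), absorption efficiency *AE*, respiration *V*O₂ (ml O₂/h)
and ammonia excretion *V*NH₄-N (µg/h), together with a per-tank diet table
(TPM/PIM/POM, mg/l). Because no such data set is publicly deposited, the
package ships a synthetic-cohort generator that reproduces the study design
(48 individuals, 16 per tank × 3 tanks, 6 monthly samplings) with a planted
latent "quality" factor linking physiology to growth, so every stage of the
pipeline is testable end to end.

## What it computes

**Energy budget** (per individual × sampling):

    OIR = CR · POM          organic ingestion rate (mg/h)
    AR  = AE · OIR          absorption rate (mg/h)
    M   = q_O2·VO2 + q_NH4·VNH4      metabolic cost (J/h)
    SFG = q_POM · AR − M             scope for growth (J/h)

with AE from the Conover ash ratio AE = (F − E)/((1 − E)·F). The energy
conversion coefficients are configurable (`EnergyCoefficients`).

**Functional representation.** Each individual's series of a variable is
smoothed by Nadaraya–Watson kernel regression, X(t) = Σⱼ yⱼK_h(t−tⱼ)/ΣⱼK_h(t−tⱼ),
Gaussian kernel, per-curve bandwidth *h* selected by generalized
cross-validation. Missing samplings are simply dropped from the sums.

**Functional diagnostics and inference.**

- *h-modal depth* D(xᵢ) = Σⱼ K(‖xᵢ−xⱼ‖₂/h_d): a center-outward ordering of
  curves; iterative trimmed-mode **outlier detection** with a
  smoothed-bootstrap cutoff.
- Pointwise **mean curves** with uniform (sup-norm) bootstrap confidence
  bands.
- Cross-sectional tests per sampling: plug-in-bandwidth **KDE** of the size
  distribution, **Kruskal–Wallis** rank ANOVA with **Tukey-HSD** post hoc on
  ranks, and a PERMDISP-style **dispersion homogeneity** permutation test.
- **One-way functional ANOVA** between fast growers (final size above the
  cohort median) and slow growers, statistic
  V = Σ_{i<j} nᵢ‖X̄ᵢ−X̄ⱼ‖₂², with a parametric Gaussian-process bootstrap
  null; and a **distance-covariance permutation test** of dependence between
  two sets of curves.

## Worked example

```python
from musselfda import (CohortConfig, generate_cohort, derive_all,
                       classify_growers, build_functional_sample, fanova,
                       trimmed_mode_outliers)
from musselfda.smoothing import trajectories_from_frame

meas, diet, truth = generate_cohort(CohortConfig(seed=42))
enriched, join_report = derive_all(meas, diet)
print(enriched.groupby("t")["SFG"].mean().round(2))

fs, _ = build_functional_sample(trajectories_from_frame(enriched, "TFW"))
print(trimmed_mode_outliers(fs, B=500, seed=1).outlier_ids)

finals = enriched[enriched.t == 150].set_index("individual_id")["TFW"]
labels, excluded = classify_growers(finals, "TFW")
cr_fs, _ = build_functional_sample(trajectories_from_frame(enriched, "CR"))
res = fanova(cr_fs, labels, B=500, seed=2)
print(f"CR functional ANOVA: V = {res.statistic:.1f}, p = {res.p_value:.4f}")
```

prints

```
t
0.0      5.51
30.0     6.10
60.0     6.39
90.0     6.55
120.0    6.93
150.0    6.24
Name: SFG, dtype: float64
['M23', 'M31']
CR functional ANOVA: V = 1750.5, p = 0.0020
```

Mean scope for growth sits around 6 J/h across samplings; two individuals
have anomalous weight trajectories; and the fast-growing half of the cohort
(final TFW above the 1.47 g median) has clearance-rate curves that differ
from the slow half at the smallest p-value the 500-resample bootstrap can
resolve — the planted feeding advantage is recovered.

The same analysis is available from the shell:

```bash
musselfda simulate --seed 42 --out data/
musselfda derive --measurements data/measurements.csv --diet data/diet.csv --out data/
musselfda run-all --seed 42 --out results/
```

`run-all` executes the fixed stage order (derive → smooth → outlier
exclusion → cross-sectional tests → even-start subsample → median split →
functional ANOVA report) and writes enriched data, curves, the outlier
report, test tables, the group report, a manifest and a log; the whole run
is a pure function of (data, config, master seed).

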