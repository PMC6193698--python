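# Methods

This note documents the models, estimators and design choices behind
`musselfda`, in the spirit of a statistical software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Energy budget

Scope for growth is the classical physiological energy balance for
suspension feeders: the energy absorbed from food minus the energy spent on
maintenance,

    SFG = q_POM · AE · CR · POM − (q_O2 · VO2 + q_NH4 · VNH4)   [J/h].

The package computes it stepwise (OIR = CR·POM, AR = AE·OIR,
M = q_O2·VO2 + q_NH4·VNH4, SFG = q_POM·AR − M) so each intermediate is
available, and the identity SFG + M = q_POM·AE·CR·POM holds to machine
precision — asserted on 10⁴ random records.

The conversion coefficients are not universal constants; the defaults are
the values in routine use in the mussel SFG literature:

| coefficient | default | units | meaning |
|---|---|---|---|
| `q_O2`  | 20.33   | J/ml O₂  | oxycaloric coefficient |
| `q_NH4` | 0.02483 | J/µg NH₄-N | ammonia-N excretory energy |
| `q_POM` | 17.9    | J/mg | energy content of absorbed organic matter |

All three are overridable per run; absolute SFG values are only comparable
across analyses using the same coefficients.

QC rules, chosen to surface data problems rather than bias summaries:
an outflow particle concentration above the inflow (impossible depletion,
usually counter noise) sets CR = 0 with a warning; a Conover ratio below
zero (feces more organic than food) is **retained and flagged**, not
truncated, because truncation would bias group means upward. Measurements
are joined to their tank's diet by nearest sampling time within ±3 days;
unmatched records are listed in a join report and never silently dropped.

## 2. Functional representation

Each individual × variable series (6 monthly points, missing values
allowed) is treated as a noisy discretization of a smooth function and
estimated by the Nadaraya–Watson kernel smoother with a Gaussian kernel.
The estimator is a convex combination of the observations, so smoothed
curves never leave the observed range; the tests assert this on random
inputs.

Bandwidths are selected per curve by generalized cross-validation,

    GCV(h) = (1/n) Σᵢ [ (yᵢ − X̂(tᵢ)) / (1 − tr(S_h)/n) ]²,

minimized over 25 log-spaced candidates from half the minimum sampling gap
(below which the smoother approaches interpolation) to the full time span
(above which it approaches a constant). Ties — exact on noiseless constant
data — break toward the larger, smoother bandwidth. Candidates where
tr(S_h)/n ≥ 1 are treated as infinite GCV; if no candidate yields a finite
score the trajectory is named in the error. Curves with fewer than 3
observed points are excluded with a logged skip report rather than
unreliably smoothed. All curves of a variable are evaluated on a common
equispaced grid (default 101 points) spanning the cohort's observation
window.

## 3. Depth, outliers, bands

Curve centrality uses the h-modal depth, D(xᵢ) = Σⱼ K(‖xᵢ−xⱼ‖₂/h_d), with
the L² norm by trapezoid quadrature on the common grid and h_d the 15th
percentile of the pairwise distances (the cited implementation's default).
Depth ordering is invariant to adding a common curve to every row and to
jointly rescaling all curves; degenerate samples (all curves identical)
return equal depths.

Outliers are detected iteratively: compute depths; estimate a cutoff C by a
smoothed bootstrap (resample the active curves with replacement, add
Gaussian noise, record each replicate's 1% depth quantile, C = median over
B replicates); flag curves with depth < C; remove and repeat (at most 5
passes). The procedure is deterministic given its seed.

Two numerical choices here matter and were set by simulation at the
procedure's own null (homogeneous Gaussian-process samples, n = 48,
B = 200):

- the depth-kernel bandwidth h_d is **held fixed** across bootstrap
  replicates at the value estimated from the observed sample — recomputing
  it inside replicates full of near-duplicate resampled curves puts the
  bootstrap depths on a different scale from the observed ones;
- the smoothing noise sd is **0.4 × the pointwise sd** of the curves.
  Much smaller noise leaves resampled sets without tails (duplicates raise
  the kernel-depth floor), inflating the cutoff until ~10% of clean curves
  are flagged; at 0.4 the replicates regenerate the sample's tails and the
  null flag rate sits at the intended ~1% while a +10 sd (even +6 sd)
  planted curve is flagged essentially always. Both measured in
  `tests/test_acceptance.py` and the acceptance script.

The `trim` parameter (default 0.1) defines the 10%-trimmed-mode central
curve (`center_`, the mean of the deepest 90%), reported for
interpretation.

Mean curves carry uniform bootstrap bands: the band radius is the `level`
quantile of sup-norm deviations of B resampled means from the observed
mean, so the band contains the observed mean by construction and its
empirical coverage of the true mean is near nominal (checked at 95% over
simulated Gaussian-process cohorts).

## 4. Cross-sectional tests

Per-sampling distributions are summarized by a Gaussian KDE whose bandwidth
comes from a two-stage direct plug-in (Sheather–Jones family): normal-scale
ψ₈, kernel estimates of ψ₆ and ψ₄, then h = (R(K)/(ψ̂₄n))^{1/5}. It tracks
R's `bw.SJ(method = "dpi")` within a few percent on the tested designs (an
R oracle test runs when `Rscript` is available).

Homogeneity across samplings uses Kruskal–Wallis (mid-rank tie correction;
identical pooled data returns H = 0, p = 1) with Tukey-HSD post hoc applied
to the pooled mid-ranks, keeping the inference rank-based; a raw-scale
option exists. Dispersion homogeneity uses the distance-based PERMDISP
scheme: reduce each observation to its distance from its own group centroid
(|x − x̄_g| univariate; Euclidean, or optional spatial median, for
multivariate), compute the one-way ANOVA F on these distances, and obtain
p by permuting the *precomputed* distances among groups,
p = (1 + #{F* ≥ F})/(1 + n_perm). Permuting distances rather than raw
observations makes the test blind to location differences between groups —
a property the tests assert — which is the point: it tests spread, not
level. Repeated measures of the same individuals at different samplings are
treated as independent groups, as is conventional for these tests; the
functional machinery is what respects the longitudinal structure.

## 5. Group analysis

Fast/slow growers are defined on an even-start subsample (first-sampling
shell length within 21 ± 0.5 mm after rounding to the 0.1 mm caliper
precision — about half of a default cohort) by a strict median split of
final size; individuals exactly at the median are excluded and listed. Both
final-L and final-TFW criteria are run.

The functional ANOVA statistic is V = Σ_{i<j} nᵢ‖X̄ᵢ−X̄ⱼ‖₂². Its null
distribution is approximated by a parametric bootstrap: group mean curves
are simulated as zero-mean Gaussian processes with each group's estimated
covariance at its own sample size (implemented exactly, without forming
the covariance matrix, as X_c'z/√((n−1)n) with z standard normal), and V
recomputed B times; p = (1 + #{V* ≥ V})/(1 + B), so the smallest reachable
p is 1/(1+B). A label-permutation null is available as a robustness
alternative. Empirical size at α = 0.05 is within the tested ±2-point band
(500 replicates; a 2000-replicate check puts it near 5.7%).

Dependence between two curve sets (e.g. growth vs feeding) uses squared
distance covariance on the L² distance matrices, with a permutation null
over the pairing of individuals. "Functional correlation" has no single
canonical test; distance covariance was chosen as a generic dependence
measure with exact permutation inference, and the choice is recorded in the
run manifest via the method name.

The group-comparison report emits one row per criterion × variable
(9 variables: L, TFW, SFG, CR, OIR, AE, AR, VO₂, VNH₄-N) with statistic,
p-value, B, seed and group sizes; variables with too few usable curves are
marked not-computed with the reason.

## 6. Synthetic cohorts

The generator emulates the monitored-cohort design the analysis assumes:
48 individuals, 16 per tank × 3 tanks, samplings at days 0–150 in 30-day
steps, initial shell length ~ N(20.5, 0.5²) mm rounded to 0.1 mm, initial
TFW ~ N(0.66, 0.089²) g, per-tank diet POM constant within each sampling
and drawn from [0.673, 0.734] mg/l with organic fraction in [0.72, 0.75].

Each individual carries a latent quality qᵢ ~ N(0, 1). Rates are

    rate_i(t) = baseline · (TFW_i(t)/0.66)^b · (1 + λ q_i) · noise,

with multiplicative loadings λ_CR = +0.20, λ_AE = +0.10 (additive clamp to
[0,1] after noise), λ_VO2 = λ_VNH4 = −0.08 — the energy-acquisition plus
metabolic-efficiency reading of growth variability — and allometric
exponents b = 0.4 (CR), 0 (AE), 0.7 (VO₂, VNH₄). Baseline magnitudes
(CR 1.5 l/h, AE 0.55, VO₂ 0.25 ml/h, VNH₄ 4 µg/h) are order-of-magnitude
placeholders: the generator targets statistical structure, not calibrated
physiology. Between-individual rate noise inflates by 1.15 per sampling,
reproducing the increasing dispersion of physiological rates over time.

Growth is mechanistic rather than a named growth curve: between samplings,
TFW increases by `growth_gain` (3.5·10⁻⁵ g/J) times the accumulated
positive SFG implied by the *recorded* (noisy) rates, and L follows
isometrically (L ∝ TFW^{1/3}). Two consequences are deliberate:
size dispersion grows across samplings because quality compounds, and
`derive_all` applied to the generated raw columns reproduces the
generator's internal SFG bit for bit (the generator associates the
arithmetic identically), so the whole pipeline can be validated against
ground truth. A consequence worth noting for interpretation: because
absolute metabolic rates scale with the body mass that fast growers
accumulate, the fast group's raw VO₂ curves end up *above* the slow
group's despite the negative efficiency loading — the size confound that
motivates measuring physiology during, not after, divergence. The planted
sign is visible in the size-standardized rate, and the recovery test
checks it there.

`plant_outliers` shifts chosen individuals' whole trajectories by multiples
of a variable's pooled sd; `degrade` knocks out rate cells independently
(rate < 0.3, since smoothing needs ≥3 points) while never touching
first/last size measurements.

What passing tests on these cohorts do **not** show: robustness to real
measurement error structure (serial correlation within a sampling day,
tank effects — available but off by default — or biologically calibrated
rate magnitudes). The generator's role is to verify statistical machinery
against known ground truth, not to simulate mussels.

## 7. Pipeline, seeds, determinism

`run()` executes a fixed stage order: derive → smooth → detect and exclude
functional outliers (on the L and TFW curve sets) → cross-sectional tests →
even-start subsample → median split → functional ANOVA report. Outlier
exclusion precedes all group inference. A single master seed generates
per-stage seeds by stable hashing of the stage name, so runs are pure
functions of (data, config, seed) — two runs with the same inputs produce
byte-identical tables, which the tests assert. Stage failure halts with the
stage name; artifacts already written are retained. Input validation
(schema, physical ranges, duplicate (id, t) rows, diet mass balance
TPM = PIM + POM) writes a per-row violation report.

## 8. Problem sizes in the validation suite

Calibration checks use 500 simulation replicates per test (nominal 5%,
asserted within ±2 points), power and recovery 50–150 replicates, outlier
simulations n = 48 curves with B = 200 bootstrap replicates, and the
recovery pipeline the default 48 × 6 cohort with B = 500 functional-ANOVA
resamples — sizes at which every Monte-Carlo margin asserted is several
standard errors wide while the whole suite stays interactive.

## 9. Known limitations

- Cross-sectional tests ignore the repeated-measures dependence across
  samplings (documented convention; the functional tests are the primary
  inference).
- The parametric functional-ANOVA bootstrap conditions on estimated group
  covariances; with very small groups (n < ~8) the permutation variant is
  the safer choice.
- The distance-covariance test detects dependence of any form and has no
  signed interpretation.
- With B resamples, permutation/bootstrap p-values are bounded below by
  1/(1+B); reported "< .005"-style conclusions require B ≥ 200.
- Energy-budget absolute values depend linearly on the configurable
  conversion coefficients.
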