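# Methods

This note documents the models and numerical choices behind each stage
of the pipeline, the synthetic-study generator's assumptions, and the
limits of what the test suite demonstrates.

## Study design

Study day 0 is the day of the first rbST dose; the 18-day conditioning
period carries negative days. The default design administers 12 doses of
500 mg at 14-day intervals with a single 28-day gap between doses 5 and
6 (dose 6 therefore falls on day 84 and dose 12 on day 168), records
milk daily for 240 days (18 + 168 + 54), and samples milk somatic cells
on 36 fixed study days. The sampling grid is dense over the first two
dose cycles, where transcriptional responses are sharpest, and roughly
weekly-to-biweekly thereafter; any grid can be supplied. Dose cycles are
binned uniformly at the dose interval (cycle 0 = conditioning window);
an explicit edge list can override the uniform bins, since published
cycle tables sometimes use irregular edges without stating a rule.

## Amplification-curve quantification

The observable model is a logistic amplification over a constant
baseline: corrected fluorescence grows as `X(c) = X0·E^c / (1 +
X0·(E^c−1)/K)` with per-cycle efficiency `E ∈ (1, 2]` and plateau `K`.
Quantification proceeds per well:

* **Baseline.** The pre-takeoff background is estimated iteratively
  (takeoff = first of two consecutive cycles above background + 3 sd,
  background re-estimated from the cycles up to two before takeoff). A
  grid search over the background mean ± 3 standard errors then picks
  the constant baseline maximizing the best window's log-linearity r².
  The grid must be anchored this way: an unconstrained search trades a
  too-low baseline against plateau curvature and biases the efficiency
  low by ≈0.13 — far outside the ±0.05 recovery target this module is
  held to. Curves with no takeoff (background swallows the series), or
  whose total rise is below 3× the early-cycle noise sd, are flagged
  `no_amplification`.
* **Window of linearity.** Candidate windows of 4–6 consecutive cycles
  must lie above the noise floor (3 sd of the first five corrected
  cycles) and below both 90% of the observed maximum and 5% of the
  estimated amplification ceiling `K̂` (twice the fluorescence at the
  maximum cycle-to-cycle increment, which equals K at the logistic
  inflection; for pre-inflection curves `K̂` underestimates K, making
  the cap conservative). The window maximizing the r² of log10 F vs
  cycle wins; ties go to the later (higher-fluorescence) window.
* **Efficiency.** `E` is the antilog of the window's OLS slope with a
  first-order correction for logistic suppression — the local log-slope
  of a logistic is `log10(E)·(1 − X/K)`, so the raw slope is divided by
  `(1 − X̄/K̂)` over the window. The correction removes a residual
  −0.02…−0.04 systematic bias across `E ∈ [1.7, 2.0]`; measured per-well
  recovery is then unbiased with sd ≈ 0.04. The uncorrected fitted line
  is retained for the Cq crossing, which is a property of the observed
  fluorescence.
* **Amplicon mean and N0.** Per amplicon, efficiencies more than 0.05
  from the median are excluded and the rest averaged. The quantification
  threshold Nq is one common value per amplicon — the geometric mean of
  window-midpoint fitted fluorescences over its quantifiable wells — so
  that `N0 = Nq / Ē^Cq` is comparable within an amplicon. Wells whose
  fitted window does not bracket Nq are flagged as extrapolating. Only
  wells whose own efficiency strays more than 0.15 from the median are
  denied an N0: per-well E does not enter N0 (the amplicon mean does),
  so moderate E scatter is no reason to discard a reaction.

N0 carries arbitrary per-amplicon units; all downstream use is through
within-amplicon ratios, which is why recovery is assessed on pairwise N0
ratios within amplicons (≥95% within ±20% over 500 simulated wells
spanning four orders of magnitude in X0).

## Session correction

Runs performed in different sessions differ by multiplicative factors.
The ratio matrix holds, for each session pair, the geometric mean over
shared conditions (gene × group by default; gene × animal available) of
the condition-mean ratio. The default estimator takes each session's
factor as the geometric mean of its matrix row, renormalized to overall
geometric mean 1 so corrected data keep their scale; the optional
maximum-likelihood estimator iterates a support-weighted least-squares
refinement in log space (Jacobi iterations, convergence 1e-10), which
matters only when sessions share conditions unevenly. With a complete
session × condition design the row-mean estimator is exact (the log
ratio matrix is rank-one antisymmetric), so residual ratios vanish up to
floating point even on noisy data. Disconnected session graphs are an
error naming the unbridgeable pairs. Correction is division by the
factor and is deliberately not idempotent.

## Reference-gene stability

BestKeeper-style descriptives per candidate: the dispersion statistic
`dev` is the mean absolute deviation of Cq from the geometric-mean Cq
(the cited tool's convention), reported alongside the ordinary sample
sd; a candidate with dev > 1 cycle is inconsistent. The BestKeeper index
is the per-sample geometric mean of candidate Cqs; it is built from the
consistent candidates only (a grossly unstable candidate would corrupt
the very index used to judge the others), and every candidate is
correlated against it (Pearson r, two-sided t-transform p, no
multiplicity correction — the p-values are descriptive). Recommended
references are consistent candidates with r ≥ 0.7.

## Relative expression and inclusion

Triplicate N0s are aggregated by arithmetic mean over quantifiable
replicates (geometric option available), with the replicate CV recorded;
a gene-sample with no quantifiable replicate is undetected. Relative
abundance is `N0_target / geomean(N0_UXT, N0_RPS9, N0_GPAM)`; samples
missing any reference are un-normalizable and excluded with a recorded
reason. The inclusion filter drops genes first, then samples: a gene
must be detected in at least `100 − max_missing_pct`% of samples, after
which any sample with a hole in the retained panel is excluded. With
structurally complete input the strict 0%-missing criterion reproduces
the nine-gene panel (IGF1R, CCND1, TNF, IL1B, SIRT2, EEF1G, MFGE8, LTF,
TPD52L2); for raw-curve input the pipeline defaults the gene threshold
to 10%, because sporadic technical well failures (a few percent of
gene-samples losing all three replicates) would otherwise annihilate
every gene — the gene-level criterion targets systematic non-detection,
the sample-level criterion stays absolute. The filter is idempotent.

## Univariate statistics

Normality per group by Lilliefors-corrected Kolmogorov-Smirnov (gate
α = 0.05), equality of variances by Levene (center = mean). Two normal
groups: t-test, pooled when Levene passes, Welch otherwise; any
non-normal group: Mann-Whitney U, exact when min(n) ≤ 8 and the pooled
sample is tie-free, tie-corrected normal approximation otherwise. All
tests two-sided, star-coded at 0.05/0.01/0.001. Measured type-I error of
the full gated policy is ~5% (4–6% band over 2000 null simulations).
Milk yields are compared per dose cycle on animal-day values (per-animal
cycle means available); the % production difference is computed day-wise
as `100·(mean_treated − mean_control)/mean_control` and then averaged
within the cycle, which is the only reading that gives the difference a
within-cycle sd.

## Multivariate screening

Columns are log10-transformed, mean-centered and Pareto-scaled (divide
by √sd). PCA is fitted by NIPALS (strict convergence 1e-12 on the
relative score change, up to 2000 iterations; a soft 1e-7 acceptance
covers near-degenerate eigenvalue pairs, whose power-iteration
convergence is geometrically slow but whose exact rotation is
statistically immaterial). Hotelling's T² uses the chemometrics limit
`A(N−1)(N+1)/(N(N−A))·F₀.₉₅(A, N−A)` (the (N−1) variant is a flag);
DModX is the residual distance normalized by the pooled residual sd with
critical value `√F₀.₉₅(K−A, (N−A−1)(K−A))`. Outlier exclusion is a
single pass over the union of the two 95% criteria — no iterative
refitting.

OPLS-DA repeats (predictive weight from X'y → orthogonal component from
the predictive loading's y-orthogonal part → deflation) and fits the
final predictive component on the deflated matrix. The orthogonal
component count is chosen by a Q²-improvement rule (> 0.01 per added
component, max 3) under deterministic 7-fold cross-validation (samples
sorted by id, assigned round-robin); Q² = 1 − PRESS/SS. CV-ANOVA
compares PRESS against the class-mean residuals with d1 = fitted
components and d2 = N − d1 − 1, the published construction for OPLS
models; PRESS ≥ SS truncates F at 0. The predictive score is oriented so
the treated-class mean is positive, making the S-plot's upper-right
corner mean up-regulated-in-treated reproducibly; `p1 = t'x/(N−1)`,
`p(corr)1 = p1/(sd(t)·sd(x))`. Biomarkers are ranked by |p(corr)1| (ties
by |p1|) with a 0.4 panel threshold. A model whose predictive weight
norm vanishes is flagged uninformative rather than fitted.

Screening new samples projects them with the training preprocessing
parameters, removes the orthogonal variation with the training loadings,
and flags samples whose predictive score exceeds the control
population's 95th percentile; samples missing a panel gene are rejected
with a reason, never silently scored.

## Synthetic-study generator

The generator reproduces the statistical structure the analysis assumes,
not mammary-gland biology. Per gene-sample, log10 abundance = baseline
mean + between-animal effect + per-sample RNA-loading effect (common to
all genes of a sample, cancelled by reference normalization) +
log10(dose effect) + noise. The dose effect is a unimodal pulse
`1 + amplitude·g(τ)` in days τ since the most recent dose: zero before
onset, saturating-exponential rise to 1 at the peak day, exponential
decay with the washout constant; pulses do not accumulate across doses,
and control animals and pre-dose days never receive effects. Defaults:

* Strong responders — CCND1 (amplitude 3.0, onset 1 d, peak 8 d), IGF1R
  (3.0, onset 0, peak 7 d, fast rise τ = 0.35 d so the day-1 effect is
  near-maximal), TNF and IL-1β (3.5, onset 2 d, peak 10 d — the
  cytokines peak in the second week of a cycle). All wash out below 5%
  of peak by 28 days (washout τ = 6 d).
* Erratic responders — SIRT2 (1.2), TPD52L2 (0.4), EEF1G (0.3) respond
  to any given dose with probability 0.15–0.25 per animal × dose,
  reflecting that their responses appear in isolated cycles only.
* Noisy non-responders — LTF, MFGE8, CTNNAL1 (CTNNAL1 with 25%
  per-sample dropout, so the inclusion filter removes it organically).
* Never detected — IGFBP3, IGFBP5, COL3A1, ESR2; IGF1 is detected per
  animal with probability 1/6.
* References — UXT, RPS9, GPAM: non-responsive, low dispersion.

Baselines are calibrated to the reference-normalized scale: the day-1
IGF1R control mean is ≈0.09 and the treated mean ≈0.35 (group-mean ratio
≈4). Between-animal sds are small (0.05 log10) relative to within-animal
noise (0.16–0.35): with only three control animals, larger between-animal
variance aliases into apparent class signal at rates incompatible with a
clean four-marker S-plot, and reference normalization removes much
between-animal scale in practice.

Milk yield follows Wood's lactation curve `a·t^b·e^(−ct)` in days in
milk (peak ≈38 kg near day 55 under the defaults; treated cows start at
67 days in milk, controls at 75), scaled per animal (log-normal, sd
0.12) and, for the treated group, by a baseline herd-imbalance factor
1.13 — the two groups of this small herd differed by ~19% before any
dose, which no treatment term can produce — plus a treatment boost
(28%) that ramps over 14 days, tracks dose coverage (decaying when more
than one interval passes without a dose, hence the trough during the
28-day gap) and fades after the last dose. Amplification curves follow
the logistic model above with per-gene efficiency (default 1.9), plateau
3000, baseline 100 ± jitter, additive noise sd 1, a multiplicative
session factor (log-normal, sd 0.35, geometric mean 1; sampling days are
grouped six per session), and X0 proportional to true abundance;
undetected gene-samples yield flat baseline-only wells. All randomness
descends from a single seed.

What the generator does **not** emulate: pharmacokinetics, mastitis and
other confounders (a per-animal covariate hook exists but is
unimplemented), injection-site effects, plate-position effects,
probe-chemistry differences, and the withdrawal undershoot visible in
the real gap-cycle milk data. Passing tests therefore demonstrate that
the pipeline recovers structure *of the assumed form*; they cannot
certify behavior under violations of that form.

## Problem sizes

The test suite and acceptance script size their simulations to run on a
single CPU in about a minute each: 500 wells for curve recovery, 2000
null comparisons for type-I calibration, 100 permutations and 500 null
datasets for the OPLS-DA calibration, 100 replicate studies (each ≈300
samples × 18 genes at the expression level) for marker recovery, and 8
replicate studies for the screening-rate contrast. Full raw-curve
pipeline runs (17 496 wells) take ≈45 s and are exercised once on a
reduced sampling grid.

## Known limitations

* The curve model assumes a constant baseline and a logistic plateau;
  drifting baselines or biphasic plateaus will degrade the window search
  (the per-well flags expose this, and such wells fall back to
  `poor_fit`).
* CV-ANOVA degrees of freedom are a convention; with ~200+ samples the
  test is insensitive to the exact d1.
* The small-herd design (3 vs 6 animals) makes all samples
  pseudo-replicates of nine animals; the pipeline follows the original
  per-sample analysis and does not fit animal-level random effects.
* Session-factor estimation assumes purely multiplicative run effects;
  additive or gene-specific batch effects are out of scope.
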