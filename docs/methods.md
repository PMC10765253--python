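# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix.

## Spectral estimation

A voxel's time series (length N, repetition time TR) is linearly detrended
per voxel and transformed to a one-sided periodogram on the `floor(N/2)`
positive DFT bins `k/(N·TR)`, `k = 1..floor(N/2)`.  The DC bin is excluded
everywhere: detrending drives it to ~0, and excluding it makes a band such as
"0–0.1164 Hz" well defined.  Power is the raw squared DFT magnitude `|X_k|²`;
Parseval's identity holds with two-sided weights 2 (interior bins) and 1
(Nyquist bin at even N), and is tested at 1e-6 relative tolerance.

**Band membership** is half-open on bin centres, `f_low < f ≤ f_high`, with a
shared absolute tolerance of 1e-9 Hz on both edges.  Abutting bands therefore
partition the axis: fALFF over disjoint bands covering (0, Nyquist] sums to 1
within 1e-10 (tested).

**ALFF** is the mean of `sqrt(power)` over in-band bins.  A `mean_over="all"`
switch divides by the total bin count instead — the two differ by the
constant (band bins)/(total bins), which cancels in fALFF; the in-band mean
is the default.  **fALFF** is the ratio of amplitude sums (band over full
spectrum).  Because bin counts are fixed, this equals the ratio of
bin-count-weighted means; the sum form is preferred because it stays
unambiguous when filtering has zeroed out-of-band bins.  Voxels with zero
total amplitude yield NaN, never 0.

**Filtering** is an ideal frequency-domain mask (retain in-band coefficients
and conjugates, zero the rest including DC).  No FIR/IIR design is offered:
the analyses specify exact band edges, and ideal masking makes
filter-then-spectrum identical to masking the spectrum, which the tests
exploit.

## Reference-ROI z-scoring and regional aggregation

fALFF maps are standardised within participant against frontal grey matter:
`z = (fALFF − mean_ref)/sd_ref`, with the sample (n−1) standard deviation
(the population/sample choice is negligible at ROI sizes but must be fixed
for reproducibility).  The constants used are recorded in the output.
Anterior-circulation referencing preserves sensitivity to a hypothesised
anterior-vs-posterior differential, which whole-brain referencing would
dilute.  Missing (undefined-fALFF) voxels propagate as missing; regions whose
voxels are all missing keep their row with NaN and a zero voxel count.

The default analysis roster has 15 non-reference regions — midbrain, pons,
medulla, bilateral amygdala/hippocampus/thalamus/insula/visual cortex,
midline hypothalamus, and one cortical control region — so the region factor
carries 14 degrees of freedom.  The exact laterality composition is
configurable; CSF is labelled but excluded from group-level modelling.

## Propensity matching

The propensity score is a maximum-likelihood logistic regression of the
hypertension indicator on age, sex (male = 1) and BMI with intercept.
Constant covariate columns are dropped (aliased with the intercept), so a
no-signal table degrades to the intercept-only fit whose fitted probability
is the treated prevalence.  Matching is greedy 1:1 nearest-neighbour on the
logit of the propensity, without replacement, treated units in descending
propensity order, ties broken by participant id — emulating MatchIt's
documented default.  No caliper is applied by default; an optional caliper is
expressed in logit-propensity standard deviations.  An exhausted donor pool
leaves the remaining treated unmatched (flagged, not an error).

With the default full-scale configuration (2054 treated vs a 1724-strong
donor pool) the pool is exhausted, reproducing the 2054/1724 asymmetry of the
motivating design.  Note the statistical consequence, which the acceptance
report surfaces honestly: when every donor is used, matching fixes sample
sizes but cannot improve covariate balance — the matched treated subset is
the high-propensity (older, heavier) end of the treated pool.  Balance
properties are therefore demonstrated in donor-rich configurations
(e.g. 200 treated vs 300 donors), where matching drives the covariate SMDs
toward zero and the baseline-table pattern (age/sex/BMI balanced, blood
pressure strongly different) holds in ≥ 99% of replicates.

Balance diagnostics use Welch two-sample t-tests for continuous covariates
and a Pearson chi-square test without continuity correction for sex (so the
statistic equals the textbook contingency formula); the SMD uses the
average-variance pooled sd.

## ANCOVA and effect sizes

The group-level model is OLS on participant-by-region rows:
`mean_z ~ group * region + age + bmi + sex`, with Type-II sums of squares by
default (order-invariant; the designs are near-balanced; Types I/III are a
switch).  Partial η² = SS_term/(SS_term + SS_residual).  Rank-deficient
designs raise an error naming the aliased columns.

Rows are treated as independent observations, which reproduces the classical
regional-ANCOVA design.  This is a deliberate fidelity choice with a known
cost: a participant's regional z-scores share participant-level noise (in
the generator, the participant's global amplitude scale and the sampling
noise of the reference constants), so tests of *between-participant* terms —
the group main effect and the covariates — are anticonservative.  Contrasts
that are within participant (the region main effect and the group×region
interaction, which is the scientific target) are unaffected; the
interaction's null rejection rate is calibrated (0.02–0.09 at α = 0.05 over
200 replicates, tested).  A mixed-effects extension would address the group
term but is out of scope.

**Power.**  For an F test of a term with numerator df `df1` and Cohen's
effect size f in the 2×R ANCOVA, the noncentrality is λ = f²·N and the
denominator df are N − (2·df1 + 2 + c) with c covariates (intercept, group,
region, interaction, covariates all subtracted).  Power is the noncentral-F
upper tail beyond the central-F critical value; `required_n` finds the
minimal N by doubling then bisection.  The implementation is validated
against a 200k-replicate Monte-Carlo construction of the noncentral F
(|Δ| < 0.01) and against exhaustive linear scan for minimality.

Bonferroni control across the three study analyses sets the per-test level
to 0.05/3 ≈ 0.0167.

## Synthetic data generator

The generator defines the study conditions under which everything is tested:

- **Acquisition**: 490 timepoints at TR 0.735 s (Nyquist 0.680 Hz), the
  6-minute multiband protocol scale; synthetic volumes carry an identity
  affine with 2.4 mm voxels.
- **Cohort**: hypertensive age 57.7 ± 6.7 y, BMI 27.8 ± 4.0, 60% male,
  systolic 149.0 ± 18.1 / diastolic 87.0 ± 10.6 mmHg; the normotensive donor
  pool is younger (55.5 ± 6.9), lighter (26.6 ± 4.4), less male (52%) with
  137.0 ± 17.0 / 81.2 ± 9.7 mmHg.  The covariate shifts make age, sex and
  BMI genuine confounders of the group label; blood pressure is drawn
  independently of the covariates given group.
- **Voxel signal**: band-limited Gaussian "neuronal" process (white noise
  spectrally masked into 0.01–0.08 Hz, scaled to a per-region amplitude),
  plus a slow drift sinusoid (~0.0056 Hz, below the 0.01 Hz band edge), a
  respiratory sinusoid near 0.25 Hz, a cardiac sinusoid at 1.0 Hz (60 bpm)
  whose sampled frequency aliases to ≈ 0.36 Hz — the same folding mechanism
  as in the real acquisition — and white thermal noise (sd 0.5).  Sinusoid
  frequencies are snapped to the nearest DFT bin to avoid leakage; cardiac
  and respiratory phases are shared across voxels (systemic physiology),
  drift phase is voxelwise.
- **Regional structure**: baseline neuronal amplitudes vary across the 15
  analysis regions (caudal brainstem lowest, visual cortex highest), giving
  a regional fALFF gradient by construction.  Group effects are additive
  amplitude deltas: a uniform `group_delta` (default 0.01, the tiny-effect
  regime of interest) and per-region `interaction_deltas` (default none).
  Each participant's regional amplitude is additionally scaled by
  Normal(1, 0.10) — between-participant variability that gives the
  group-level model a realistic residual.
- **CSF**: CSF voxels carry a *flat* full-band stochastic component
  (pulsatile CSF power is broadband) of sd 1.5 and the whole voxel series is
  scaled by the broadband multiplier (default 5).  Relative to parenchyma,
  CSF spectra are uniformly stronger but flatter, so ALFF(CSF) exceeds
  parenchymal ALFF while fALFF(CSF) is suppressed — this ordering holds in
  100/100 seeded replicates at a multiplier of 2.
- **Determinism**: all randomness derives from integer seeds through numpy
  seed sequences; identical configuration and seed give byte-identical
  tables, series and reports (tested).

For Monte-Carlo calibration experiments (type-I error, power curves) a
regional-level generator draws `mean_z` directly from the ANCOVA linear
model with Gaussian residuals and equal cell sizes, so the injected
interaction's Cohen's f (computed exactly by double-centring the cell-mean
matrix) maps to the noncentrality λ = f²·N without voxel-level approximation
error.  What the voxel-level generator does *not* emulate — hemodynamic
response shape, head motion, spatial autocorrelation, scanner/site effects —
bounds what passing tests say about real data: they validate the estimators
and the inferential machinery, not robustness to unmodelled artefacts.

## Pipeline

A study run chains cohort simulation → propensity matching → per-participant
voxel simulation → fALFF (broad (0, 0.1164] Hz and narrow (0.01, 0.08] Hz) →
frontal-GM z-scoring → regional means → three ANCOVAs: a seeded pilot subset
re-analysed in the broad band (the same code path with a subsetting step),
the full sample in the broad band, and the full sample in the narrow band.
Verdicts use only the Bonferroni-corrected threshold (0.05/3).  Artifacts
(TSV tables, a JSON manifest with a config hash, a plain-text report) are
byte-reproducible given the seed; a rerun with the same configuration is the
resume mechanism.

## Problem sizes

Test and acceptance experiments are scaled to desk hardware as the package's
own study conditions: cohort-level experiments run at full scale (2054/1724)
where only tabular data are involved; voxel-level studies use ~30–36
participants per group with ~220 voxels each; Monte-Carlo calibrations use
200 replicates (type-I), 150 replicates (power, at 510 and 3450
participant-region rows), and 100–200 replicates for matching and CSF
properties.  The full test suite runs in well under a minute of CPU beyond
the Monte-Carlo suites; `scripts/acceptance.py` completes in under a minute.

## Known limitations

- Group-main-effect and covariate p-values are anticonservative under
  within-participant correlation (see ANCOVA section); the interaction term
  is the calibrated quantity.
- The ideal boxcar filter has infinite impulse response in time; edge
  effects are irrelevant here because analyses operate on the spectrum, but
  filtered *series* should not be interpreted sample-by-sample near
  boundaries.
- Greedy matching is order-dependent by construction; optimal matching is
  not implemented.
- `required_n` answers the noncentral-F question exactly as posed; choosing
  the effect size f from pilot partial η² estimates inherits their sampling
  noise, which the package does not model.
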