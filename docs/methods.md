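# Methods

This note documents the models and procedures implemented in `ftcdlat`, the
parameters that matter and their defaults, the numerical choices, what the
synthetic-data generator does and does not emulate, and the package's design
decisions where the design was genuinely open.

## 1. Signal pipeline

### Processing order

The chain runs: provisional epoching with **dropout imputation on the raw
trial spans** → **heart-cycle integration** → **epoching** → **normalisation**
→ **range-based artefact rejection** → **baseline correction** → LI
derivation. Two ordering constraints drive this: imputation must precede
normalisation (a single extreme sample would otherwise distort the
per-channel scaling constant), and it must precede heart-cycle integration,
because cycle averaging dilutes a single aberrant sample roughly 17-fold at
25 Hz and a 90 bpm heart rate, after which it is no longer identifiable as a
dropout. Imputation needs trial context (the trial median and mean), hence
the provisional epoching pass.

### Heart-cycle integration

Systolic peaks are detected on the **summed** channels (`scipy.signal.find_peaks`
with a minimum inter-peak distance of `60/max_rate` s), which makes the
operation exactly symmetric under a left/right channel swap. Samples within
each inter-peak interval are replaced by that interval's per-channel mean;
edge samples take the nearest cycle's mean. The plausible heart-rate band
defaults to 40–150 beats/min. Detected inter-peak intervals longer than
`60/min_rate` s cannot be cardiac cycles — they arise when a recording has
little or no pulsatile content — and are passed through unchanged rather than
averaged away; without this guard, a long spurious "cycle" would flatten the
task-related waveform itself.

### Dropout rule

A sample is a dropout candidate if it is ≤ 0 or deviates from its trial's
median by more than `mad_k = 4` scaled median absolute deviations
(1.4826·MAD). Candidate runs of at most `max_run = 1` sample are replaced by
the mean of the trial's non-candidate samples; longer runs are deliberately
left for the range rule to catch, since a sustained excursion is an artefact,
not a blip. A trial consisting entirely of candidates is rejected as
flat/dropout. The thresholds are package choices (configurable); the
qualitative rule — substitute isolated aberrant points by the trial mean — is
the method's.

### Normalisation, rejection, baseline

Within the pipeline the per-channel scaling constant is computed over all
samples of the epochs still in play, then applied to every epoch, mirroring a
whole-recording mean-100 normalisation restricted to analysable data. The
artefact bounds default to [60, 140] normalised units (no published value
exists for this step; ±40% around the mean is permissive enough to keep
physiological responses, strict enough to reject probe transients). Baseline
correction subtracts the per-channel mean over [−12, 0) s relative to talk
onset, per epoch.

### LI, SE, CI, categories

The peak is the sample of greatest **absolute** grand-average difference
within the POI (4–14 s after talk onset), so right-dominant children get a
meaningful peak; ties break to the earliest sample. The 2 s window is clipped
at the epoch boundary if the peak sits within 1 s of it. The LI retains its
sign. The SE uses the n−1 SD of trial-by-trial window LIs divided by √n, and
the CI multiplier is the printed 1.96 normal quantile, not a t quantile — the
categorisation rule is defined with 1.96. A CI endpoint exactly at zero
counts as crossing zero (bilateral). Usability requires ≥ 12 accepted trials
and −10 ≤ LI ≤ 10. Split-half LIs assign accepted epochs to odd/even by
1-based order, and each half reruns the full grand-average + peak-window
procedure, finding its own peak — the halves are treated as two independent
mini-experiments. Percent change per artery is the POI mean of the corrected,
normalised signal, averaged over accepted epochs.

## 2. Behavioural scoring

EHI: 1 point per exclusively right-handed action, ½ for both hands, 0 for
left, over 10 actions; index = (2·score − 10)·10, the linear map through the
stated endpoints (±100). Right-handedness is strict (index > 0); an exactly
balanced child is not right-handed. QHP: 1 point per right-handed reach over
21 reaches (3 per position, 7 positions at 30° intervals, position 4 the
midline); right-handedness is strict (score > 10). Dominance-consistency
coding: the triple (fTCD, EHI, QHP) with 1 = left-hemisphere dominant on that
measure; only (1,1,1) is consistent.

DLD classification flags a measure when its value is **strictly below**
mean − 1 SD on its norm scale ("more than 1 SD below" read literally); ≥ 2
flags of 13 ⇒ DLD, else TD. Norm scales default to the conventional scale per
instrument family (IQ-type 100/15, scaled subtest 10/3, t-type 50/10) and are
supplied as a configurable measure-metadata table, since published
descriptives do not identify every instrument's scale. Recruitment exclusions:
performance IQ < 70 (the 2 SD boundary itself is included), ASD diagnosis in
either twin (excluding the pair), hearing failure, serious medical condition.

## 3. Statistics

**Linear mixed models** (LI, percent change, words, trial counts; also
sex+age and zygosity checks) use a random intercept per twin pair. For this
structure the REML criterion concentrates to one dimension in the variance
ratio γ = σ²_pair/σ²_resid, so the model is fit by profiled closed-form REML
(bounded scalar optimisation on log γ with an explicit boundary comparison at
γ = 0). A fit with σ²_pair/σ²_resid < 1e-6 is flagged singular, the pair
variance floored at 0, and the model then coincides exactly with ordinary
least squares. Fixed-effect t tests use Satterthwaite-approximate df: for a
contrast c, df = 2g²/(∇gᵀ Cov(θ̂) ∇g) with g(θ) = cᵀ(XᵀV⁻¹X)⁻¹c, the gradient
by central finite differences and Cov(θ̂) from the numerically inverted REML
information. statsmodels' MixedLM is the independent cross-check in the test
suite. Marginal means per group are computed from the fitted fixed effects at
the observed covariate distribution with each child assigned to the focal
level in turn, with t CIs at the contrast's Satterthwaite df.

**Random-intercept logistic regression** (dominance consistency,
right-handedness on both measures) integrates the pair intercept out by
21-node Gauss–Hermite quadrature and maximises the marginal likelihood over
(b₀, b₁, σ_u ≥ 0) with L-BFGS-B. The odds ratio is exp(b₁) with
profile-likelihood 95% CIs (bracketed outward from the MLE in SE-sized steps,
then Brent root-finding on the profile deviance at χ²₁(0.95)); if profiling
fails the CI falls back to Wald with a logged note. |b₁| > 15 or a
non-invertible Hessian is flagged as separation, with no OR reported.

**Multinomial multilevel model** (left/bilateral/right category):
baseline-category logit with two equations (bilateral-vs-left,
right-vs-left), a group fixed effect in each, and an independent pair-level
random intercept per equation. The random effects are marginalised by 9×9
2-D Gauss–Hermite quadrature, so the posterior has only 6 free parameters
(4 fixed effects, 2 log SDs), sampled by adaptive random-walk Metropolis:
diagonal proposals initially, then the empirical covariance (scaled 2.38²/6)
learned during burn-in, with acceptance-rate targeting at 0.25. Priors are
N(0, 10²) on fixed effects and half-normal(5) on the random-effect SDs
(weakly informative; package choices). Defaults: 4 chains × 10 000
iterations, 2 000 burn-in, thinning 10. Reported: posterior median ORs,
central 95% credible intervals, and pMCMC = 2·min(P(β>0), P(β<0)) floored at
2/n_draws. Split-chain R-hat is computed for every parameter; R-hat > 1.1
flags the result nonconverged. Identical seed and data give identical
summaries. With weakly-informative priors and small category counts the
posterior median OR sits slightly above the contingency-table OR even at zero
true pair variance (the prior keeps mass on σ > 0 and the conditional OR
exceeds the marginal one); the oracle-equivalence test therefore uses a
cohort large enough for the likelihood to dominate.

**Zero-one-inflated beta regression** (EHI index rescaled to (x+100)/200,
QHP score to x/21): mixture with point masses α₀ at 0 and α₁ at 1 and
Beta(μφ, (1−μ)φ) on the interior, logit(μ) = b₀ + b₁·group. The likelihood
factorises, so (α₀, α₁) have the closed-form multinomial MLE (the sample
proportions of exact 0s and 1s) and (b₀, b₁, φ) are maximised numerically on
the interior observations (BFGS with a Nelder–Mead fallback); b₁ gets a Wald
test from the numerical Hessian. The stated dependent variable "the logit of
the handedness measure" is undefined at exact 0/1 scores; the standard
zero-one-inflated formulation referenced alongside it is implemented instead.
The model is fit separately in the twin-1 and twin-2 subsamples (twin labels
were assigned arbitrarily, so these are random halves that remove the
within-pair dependence), and a group effect counts as significant only with
p < .05 in both.

**QHP position model**: per-position right-reach proportions (7 rows per
child) in a mixed model `proportion ~ position × group` with random
intercepts for pair and for child nested in pair — the child level is needed
because each child contributes 7 correlated rows. Position enters numerically
(1–7). This model has two variance components, so it is fit with statsmodels'
MixedLM (Wald tests); the three reported tests are position, group, and their
interaction.

**Spearman replication**: each of the 13 language measures plus performance
IQ is correlated (Spearman) with the LI — and separately with |LI| — within
each twin subsample; Holm–Bonferroni adjustment is applied within each
14-test family, and a correlation is "replicated" only if adjusted p < .05 in
both subsamples.

**Effect sizes and descriptives**: Cohen's d = (m₁ − m₂)/√((s₁² + s₂²)/2)
(unweighted root-mean variance; this pooling reproduces the reference worked
examples to 2 decimals), reported to 2 decimals. Pseudo-R² for nested mixed
models is (σ²_resid,reduced − σ²_resid,full)/σ²_resid,reduced floored at 0.
Descriptive tables print mean (±SD) for continuous variables and
count (percent to 1 decimal, group n as denominator) for flags and
categories.

**Missing data** are handled complete-case per model, with dropped-row counts
logged.

## 4. Synthetic cohort generator

The generator emulates the study conditions end to end: per child, a
two-channel velocity recording at 25 Hz (configurable, ≥ 10 Hz) with 30
trials (12 s viewing + 10 s talk + 5 s inter-trial gap ⇒ 27 s talk-onset
spacing; first onset at 14 s), base velocities 60/55 cm/s, sinusoidal cardiac
pulsatility (amplitude 12 cm/s; heart rate N(90, 8²) bpm per child, a
paediatric resting range), an early bilateral gamma-shaped activation peak
(4% of base, peaking 1.5 s after talk onset, decayed before the POI), and a
sustained lateralised plateau: the left channel gets +d/2 % and the right
−d/2 % over 4–14 s with 1 s cosine ramps. The plateau carries a gentle 1%
maximum at 9 s — evoked responses are sustained but not perfectly flat, and
the interior maximum keeps the earliest-tie peak search off the onset ramp,
where a mathematically flat plateau would park it and bias the LI low by
construction. White measurement noise (1.5% of base per sample) and
per-trial lateral-effect jitter (SD 2 % units) supply the within-child
variability that makes SEs, CI categorisation and split-half reliability
meaningful; both are configurable and can be zeroed for oracle tests.

True lateral effects have mean 2.0 and SD 2.5 % units (matching the reported
LI distribution) with a pair intraclass correlation of 0.3, implemented as
√ICC·pair + √(1−ICC)·child standard-normal components. Dominance-class
ground truth is derived by thresholding each child's true effect at the
normal quantiles of its marginal distribution (right below the 15% quantile,
bilateral in the next 18% band), which keeps the effect distribution — and
hence its ICC — untouched while realized prevalences are binomial around the
targets. `group_li_shift` (default 0, the null) shifts destined-DLD
children's effects.

Artefacts: spikes multiply ~0.5 s of signal by 1.9 (probe-movement
transients of about one cardiac cycle, so they survive cycle averaging and
land outside [60, 140] after normalisation); dropouts zero a single sample
(80%, imputable) or a ~0.5 s run (20%, forcing range rejection). Per-trial
rates default to 3% and 5%; behaviourally invalid trials occur at 8%,
yielding ~26–27 accepted trials of 30 as reported. Word counts are
Poisson(20) per trial, independent of the true effect (the null covariate).

Handedness: each child has a logistic-scale latent h ~ N(3, 3²). An EHI item
is right if h + logistic noise > 0.8, left below −0.8, both otherwise; a QHP
reach at position j is right with probability expit(h + 0.9·(j − 4)). These
defaults reproduce the reported handedness descriptives (EHI index ≈ 58 ± 58
with ~81–86% right-handed; QHP ≈ 16 ± 6 with ~75–81% right-handed) and make
the position profile monotone with a symmetric expected score of 10.5 at
h = 0.

Language scores: 14 standardised measures (13 language/literacy +
performance IQ) share an exchangeable correlation of 0.6; children destined
for DLD get a −1.3 SD shift on all language measures and −0.6 SD on IQ. The
destination probability is solved so the ≥2-of-13 classifier's expected
prevalence equals `prop_dld_target` (default 0.4, the oversampled study
ratio), using a seeded Monte-Carlo estimate of the exceedance probabilities
with and without the shift. Note the 2-of-13 rule is liberal: under the
correlated norm model an unshifted child is classified DLD with probability
≈ 0.37, which the generator treats as a property of the rule, not a bug.

**What the generator does not emulate:** real hemodynamics (the velocity
waveform is a sinusoid plus smooth activation shapes, not a physiological
pulse), probe physics, heart-rate variability within a recording, item-level
psychometrics of the instruments, age or sex effects on laterality, zygosity
differences in ICC, and DLD-handedness or DLD-laterality associations beyond
the configurable shifts. Passing tests therefore show that the pipeline and
statistics recover what was injected under realistic noise and artefact
structure — not that the defaults capture every property of real recordings.

## 5. Problem sizes in tests

Simulation-based tests use: 1000 replications for the type-I error of the LI
mixed model (200 pairs each), 500 for CI coverage and estimate recovery, 200
for logistic OR recovery (300 pairs each), a 60-child full-pipeline cohort
for split-half reliability, 13 effect levels across [−6, 6] for ground-truth
recovery, an 880-child category-discordant cohort for the MCMC oracle
equivalence (large enough for the likelihood to dominate the weakly
informative priors), and 12 permutations with short chains for the MCMC null
calibration. MCMC tests run 1–2 chains of 1 200–5 000 iterations with 5–7
quadrature nodes per dimension; the production defaults are larger (4 ×
10 000, 9 nodes).

## 6. Known limitations

* The Satterthwaite machinery covers the single random-intercept structure;
  the QHP position model reports Wald tests from MixedLM instead.
* The multinomial model assumes independent random intercepts across the two
  equations; a cross-equation correlation is not estimated.
* ZOIB inflation probabilities are intercept-only (no group effect on the
  probability of an extreme score), matching the factorised formulation used.
* Profile CIs can fail on near-separated data; the fallback is Wald with a
  flag, and genuine separation is flagged with no OR.
* The recording reader expects the package's own TSV dialect; adapters for
  other acquisition formats should align markers on talk onset.
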