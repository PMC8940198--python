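# Methods

## The unpredictability statistic

During free-play interaction a mother emits three kinds of sensory signals
to her child — auditory (vocalizing), visual (presenting or manipulating an
object the child attends to), and tactile (touching, holding). At any
instant the joint presence/absence of the three modalities is one of
2³ = 8 combination states. The stream of *distinct* states (consecutive
duplicates collapsed) is treated as a realisation of a first-order
discrete-state Markov process, and its unpredictability is the entropy
rate

H = − Σᵢ πᵢ Σⱼ p̂ᵢⱼ log₂ p̂ᵢⱼ,

with p̂ᵢⱼ the row-normalised transition frequencies, πᵢ the empirical
origin-state frequencies, and 0·log 0 = 0. Collapsing makes
self-transitions structurally impossible, so each state has 7 admissible
destinations and 0 ≤ H ≤ log₂ 7 ≈ 2.807 bits per transition. H = 0 iff
every visited row is degenerate (a perfectly repetitive pattern, e.g.
speak → touch → show toy → speak → …); H = log₂ 7 iff transitions are
uniform. Dwell times are carried through the pipeline but deliberately do
not enter the statistic: unpredictability is about the *order* of signal
combinations, not their pacing.

Choices where the construct leaves room:

- **π is the empirical origin frequency**, not the stationary distribution
  of the estimated matrix. The plug-in MLE is well defined for short and
  possibly non-ergodic observed chains; on long ergodic chains the two
  agree (tested). The stationary variant is available via
  `entropy_rate(..., origin="stationary")`.
- **No bias correction by default.** The plug-in estimate is downward
  biased for short sessions (visibly so below a few hundred transitions);
  a Miller–Madow correction is available
  (`bias_correction="miller-madow"`) but off by default so the statistic
  stays the plain plug-in quantity.
- **Low-data flagging, not dropping.** Sessions with fewer than
  `min_transitions` (default 10) transitions are flagged; exclusion is a
  pipeline-level decision.

### Timeline construction

Event intervals are half-open `[onset, offset)`; at a shared timestamp the
offset takes effect before the onset, so a behavior handover never creates
a spurious overlap state. The visual bit defaults to the *conjunction* of
mother-manipulates-object and child-attends (`attention_mode="conjunction"`),
because attention to the mother's activity is what renders the object a
visual signal to the child; `"mother_only"` is provided since coding
conventions differ on whether child attention gates the visual channel.
The no-behavior state is a full member of the state space. Sub-`epsilon`
segments can optionally be absorbed into their predecessor (default:
keep everything).

## Synthetic study conditions

No public data of this kind exist, so the generator *is* the study
population; its defaults are the published cohort conditions and are not
tuning knobs.

- **Sessions.** A one-parameter family `M(λ) = (1−λ)·C + λ·U` (C a fixed
  8-cycle, U uniform over the 7 non-self destinations) spans the entire
  entropy range with closed-form entropy
  H(λ) = −a log₂ a − 6b log₂ b, a = 1−λ+λ/7, b = λ/7 (the matrix is
  doubly stochastic, so its stationary law is uniform). H(λ) is strictly
  increasing, so any target entropy is planted exactly by monotone root
  finding (`calibrate_lambda`, round-trip error < 1e-6). Dwell times are
  exponential with mean 2 s; sessions default to 150 transitions at
  8 months and 110 at 30 months — plausible magnitudes for 10-minute play
  at 2–5 s per state visit; observed transition-count distributions are
  not published, and the manifest marks these as assumptions.
- **Cohort.** Per dyad a 4-variate Gaussian latent (entropy and
  sensitivity at both ages) is drawn with means/SDs 0.87 (0.16), 0.79
  (0.13), 5.36 (1.32), 5.27 (1.05), stabilities r = 0.296 and 0.293, and
  entropy–sensitivity correlations −0.279 / −0.146. Unspecified cross
  terms (8-month entropy with 30-month sensitivity and vice versa) are
  set to 0; the resulting matrix is positive definite. Binary depressive
  (68/356) and anxiety (33/356) trajectory classes shift 30-month
  sensitivity by −0.64 and −0.42 points; the shifts are mean-centred and
  the latent 30-month SD deflated so the configured *marginal* moments and
  correlations are honoured exactly in expectation. Sensitivity is
  truncated to the 1–7 EA scale (optionally half-point quantised);
  truncation attenuates the realised sensitivity SD by a few percent,
  which is inherent to a bounded instrument — the untruncated scale is
  available (`truncate_sensitivity=False`) for moment checks. Entropies
  are realised by calibrating λ per dyad; `mode="closed_form"` records the
  generating-matrix entropy exactly, `mode="simulate"` runs the full
  session simulation and plug-in estimation (slower, and downward-biased
  at realistic session lengths exactly as the estimator is on real data).
  Covariates (education 25.8/31.2/43.0%, income four bands, 56.2% boys,
  maternal age 31.0 ± 4.5 y) are sampled independently of the outcomes,
  so covariate-adjusted models have a known null to recover.
- **Trajectories.** Scores follow
  `score_it = intercept_c + b0_i + (slope_c + b1_i)·t + ε` with time coded
  0…T−1 over occasions so the intercept is the first (gestational week 14)
  assessment. Depressive defaults: 467 subjects, 7 occasions, classes
  370/97 with intercepts 2.95/11.24 and per-occasion slopes −0.14/−0.41;
  anxiety: 468 subjects, 6 occasions, 414/54, 2.39/11.17, −0.09/0.22.
  Residual SD defaults to 2 points (modest noise on the 0–30 EPDS scale;
  random-effect SDs default to 0). Scores are truncated to the instrument
  range, which slightly compresses the low class near 0 but leaves the
  elevated class untouched.

What the generator deliberately does **not** emulate: child-driven
dynamics beyond the attention gate, missing data (cohorts are complete;
the mixture model itself accepts missing cells), covariate–outcome
confounding, item-level questionnaire structure, and any dependence of
entropy on session length (their independence is the construct-separation
diagnostic). A green test suite therefore shows the machinery is correct
under the published moment structure, not that real dyads satisfy these
distributional assumptions.

## Growth mixture model

`GrowthMixture` fits, by EM, a K-class mixture of linear growth curves
with class-specific fixed intercept/slope, shared homoscedastic residual
variance, and mixing proportions; subject likelihoods run over observed
occasions only (missing-at-random). This is intentionally simpler than
full structural-equation mixture software: only class means, sizes and a
residual scale are identifiable from the quantities the model is screened
with, and any between-subject random variation is absorbed into σ².
Estimation details:

- best of `n_starts` (default 20) random-responsibility initialisations;
  log-likelihood is monotone within each run (asserted in tests, slack
  1e-6 for float noise); convergence at relative change < 1e-8;
- a start that collapses a class below 1/n responsibility is discarded
  with a warning and redrawn (up to 4× n_starts attempts);
- classes are reported ordered by intercept; label permutation does not
  change the likelihood, so comparisons with generating labels use the
  best permutation;
- standard errors are the conditional weighted-least-squares values given
  the final responsibilities — adequate when assignment is crisp,
  anti-conservative when classes overlap heavily;
- fit indices: BIC = −2ℓ + p·ln n; per-class mean max-posterior (0.80
  adequacy guideline); the relative classification-entropy index
  E = 1 − Σ −p log p / (N ln K) ∈ [0,1], with E ≡ 1 for K = 1 — this is
  the mixture-model classification index, distinct from the Markov
  entropy rate;
- K = 1 reduces exactly to pooled least squares (tested to 1e-6); exact
  posterior ties break deterministically to the lower class index and are
  flagged.

## Cohort analysis battery

`run_pipeline` reproduces the analysis layer on any conforming dyad
table: a covariate screen (one-way ANOVA for education/income, pooled t
for infant sex, Pearson r for maternal age), the age-comparison table
(means, SDs, paired t on d = x₈ − x₃₀), stability and cross-construct
correlations, symptom-class t-tests with group means/SDs, dummy-coded
OLS models of 30-month sensitivity (reference levels: university
education, highest income band, girls, low-symptom class) with
per-coefficient partial η² = t²/(t² + df_resid), and the
transitions-vs-entropy diagnostic. Conventions: two-sided p throughout;
classical pooled-variance t (no Welch correction), matching df = n−2
reporting; coefficients are unstandardized (the class coefficient is
commensurate with the raw group difference); listwise deletion; **no
multiple-testing adjustment** (raw p-values, stated in the report
header). Singleton factor levels are dropped from the screen ANOVAs, and
a declared GLM reference level absent from a small sample falls back to
the modal level (recorded in the header). Every report carries n, the
seed if supplied, and a config hash. Treatment-coded OLS p-values differ
from Type-III tests only in unbalanced multi-factor designs; the
generator's factors are sampled independently, so the distinction is
immaterial for the planted checks.

## Problem sizes

Default verification runs use: exhaustive oracle comparison on all
duplicate-free sequences of length ≤ 8 over 3 states; estimator
consistency at 10⁵ transitions × 5 random matrices; cohort calibration at
10⁵ dyads (closed-form entropies); 200 replicate cohorts of n = 103 for
the paired-t self-consistency check; 20 simulation seeds × 20 EM starts
for trajectory recovery; 1000 null replicates for type-I error. These
sizes give Monte-Carlo error comfortably inside each stated tolerance.

## Known limitations

- The plug-in entropy estimator is biased low at realistic session
  lengths (~150 transitions); cross-age comparisons on equally long
  sessions are unaffected in expectation, but absolute levels are not
  bias-corrected unless Miller–Madow is enabled.
- The mixture model does not estimate random-effect covariance
  structures; posterior crispness is overstated when true trajectories
  vary within class.
- The generator's truncation of sensitivity to 1–7 means configured
  moments are latent-scale quantities; realised moments are attenuated by
  the clip (a few percent at the default parameters).
- Stationary-π entropy requires an irreducible visited submatrix; for
  short fragmented sessions the empirical-π default is the safer choice.
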