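# dyadstats

Tools for quantifying the **unpredictability of caregiver sensory
signals** in mother–child interaction and for the longitudinal cohort
analysis built around that statistic. Intended for developmental and
biobehavioral researchers working with interval-coded observational data
(e.g. Observer-style exports) and repeated questionnaire measures.

## What it computes

During free play a mother provides three kinds of sensory input —
auditory (vocalizing), visual (manipulating an object the child attends
to), and tactile (touch/holding). At every instant the joint
presence/absence pattern is one of 2³ = 8 combination states. The
sequence of distinct states is modelled as a first-order Markov process
and its unpredictability is the **entropy rate**

H = − Σᵢ πᵢ Σⱼ pᵢⱼ log₂ pᵢⱼ  ∈ [0, log₂ 7 ≈ 2.807] bits,

where pᵢⱼ are the transition probabilities between signal combinations
and πᵢ the origin-state frequencies; self-transitions are structurally
excluded because consecutive duplicate states are collapsed. H = 0 is a
perfectly repetitive signalling pattern, H = 2.807 fully random
switching.

Around the statistic the package provides:

- `events` — parsing and validation of delimited event logs, interval
  sweep into the 8-state timeline (half-open intervals, configurable
  child-attention gating of the visual channel), duplicate collapsing;
- `entropy` — transition-model estimation and the entropy-rate statistic
  (empirical or stationary π, optional Miller–Madow correction);
- `mixture` — a statsmodels-style latent growth mixture model
  (`GrowthMixture(...).fit()` → results with class intercepts/slopes,
  proportions, BIC, posterior probabilities, the 0–1 classification
  entropy index, `summary()` and `plot()`);
- `stats` — paired/independent t, Pearson r, one-way ANOVA, dummy-coded
  GLMs with partial η², and `run_pipeline` producing the full cohort
  report (stability, cross-construct correlations, symptom-class
  effects, covariate-adjusted models);
- `simulate` — a calibrated synthetic-cohort generator: a cycle↔uniform
  family of transition matrices with closed-form entropy spanning
  [0, 2.807], exact entropy planting via `calibrate_lambda`, session
  rendering back to event intervals, and two-class symptom-trajectory
  simulation.

## Worked example

```python
from dyadstats import (
    CohortConfig, GrowthMixture, TrajectoryConfig, calibrate_lambda,
    make_generator_matrix, simulate_session, entropy_from_sequence,
    build_state_timeline, collapse_to_state_sequence,
    simulate_cohort, simulate_symptom_trajectories, paired_t,
)

# one session with a planted entropy rate of 0.87 bits
lam = calibrate_lambda(0.87).lam                       # 0.1466
record, truth = simulate_session(make_generator_matrix(lam),
                                 n_transitions=150, rng=8)
seq = collapse_to_state_sequence(build_state_timeline(record))
rec = entropy_from_sequence(seq, dyad_id="d0", age_point="8mo")
print(rec.entropy_bits, rec.n_transitions)
# 0.521 bits over 150 transitions  (plug-in estimates run low at short n)

# a 103-dyad cohort with the default two-age structure
cohort = simulate_cohort(CohortConfig(n_dyads=103), rng=8)
t = paired_t(cohort.entropy_8mo, cohort.entropy_30mo)
print(t)   # t(102) = 4.283, p = 4.2e-05, mean drop 0.079 bits

# two-class growth mixture on synthetic depressive-symptom scores
traj, labels = simulate_symptom_trajectories(TrajectoryConfig(), rng=8)
res = GrowthMixture.from_long(traj, k=2).fit(n_starts=20, seed=8)
print(res.summary())
```

```
Latent growth mixture model (EM)
================================================================
subjects: 467    occasions: 7    classes: 2
log-likelihood: -6907.395    BIC: 13851.668    residual SD: 1.872
classification entropy: 1.000  (>0.80 indicates crisp assignment)
----------------------------------------------------------------
class    prop    intercept        slope  avg post
    0   0.820   3.005 (0.065) -0.128 (0.018)     1.000
    1   0.180  11.369 (0.139) -0.392 (0.039)     1.000
================================================================
```

The paired t says 8-month sessions are reliably less predictable than
30-month sessions in this cohort; the mixture recovers a large
low-stable class starting near 3 EPDS points and a small elevated class
starting above 11 and declining, with crisp posterior assignment.

A command-line layer wraps the same functions:

```bash
dyadstats simulate --out-dir demo --seed 5 --emit-events 3
dyadstats entropy --input demo/event_log.tsv --out demo/entropy.tsv
dyadstats trajectories --scores demo/trajectories.tsv --k 2 --out demo/gmm
dyadstats analyze --cohort demo/cohort.tsv --out demo/report
```

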