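# cuecombine

Audiovisual cue-integration analysis for 2IFC spatial-localization
experiments, runnable end-to-end on synthetic data.

The package simulates model observers (reliability-weighted fusion,
cue switching, fixed-weight), fits constrained cumulative-Gaussian
psychometric functions under a betabinomial (or binomial) likelihood,
derives maximum-likelihood-estimation (MLE) predictions for sensory
weights and audiovisual variances, and runs parametric-bootstrap and
group-level inference over a whole simulated cohort — including the
adaptive-staircase reliability matching, participant exclusion and
replacement rules, and both power analyses.

## Modules

| module | contents |
| --- | --- |
| `cuecombine.observer_sim` | observer specs, JND-scaled designs, trial/cell-level response simulation, transformed weighted up/down staircases, trial-table I/O |
| `cuecombine.psychometric_fit` | psychometric function, binomial/betabinomial likelihoods, joint constrained fit (shared lapse/overdispersion, shared AV slope), saturated model, batched refits |
| `cuecombine.mle_model` | inverse-variance weights, fused variance, predicted conflict PSEs, empirical weight estimators (pooled and per-condition with bias correction) |
| `cuecombine.bootstrap_inference` | parametric bootstrap, percentile CIs, goodness-of-fit deviance test, within-subject contrast tests |
| `cuecombine.group_stats` | one-sided paired t/Wilcoxon with a normality screen, effect size dz, one-sided JZS Bayes factors, Greenhouse-Geisser repeated-measures ANOVA, closed-form and simulation-based power |
| `cuecombine.pipeline` | cohort orchestration: screening, staircases, exclusion/replacement, fitting, predictions, bootstrap, group battery, artifact output |
| `cuecombine.cli` | `cuecombine` command-line interface |

## CLI

```bash
# full synthetic replication (config is YAML; all randomness seeded)
cuecombine replicate -c config.yaml -o out/

# stage by stage
cuecombine simulate  -c config.yaml -o tables/
cuecombine fit       tables/p000.csv -o fit.json
cuecombine predict   fit.json -o tidy.csv --disparity 2.83
cuecombine bootstrap tables/p000.csv fit.json -o boot.json --disparity 2.83 --n-boot 5000
cuecombine group     tidy.csv -o report.json

# power analyses
cuecombine power --dz 0.58 --n 36                 # closed form, one-sided
cuecombine power --deviation 0.06 --n 36 --n-experiments 100
```

A minimal config:

```yaml
n_target: 36
seed: 1
sigma_A_range: [1.5, 3.0]
lapse_range: [0.0, 0.04]
eta_range: [0.05, 0.15]
policy_mix: {mle: 1.0}
n_per_cell_main: 40
n_boot: 5000        # reduce for quick runs
likelihood: betabinomial
```

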