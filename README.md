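# xcsr-extubation

Rule-based prediction of extubation outcome and rule-derived feature
importance, built around an XCSR — an accuracy-based learning
classifier system for real-valued inputs.

## The problem

Roughly 15–20% of ICU patients who pass a spontaneous breathing trial
(SBT) still fail extubation (respiratory failure or death within 48 h
of tube removal), and which of the many bedside variables actually
carry the decision-relevant signal is unclear.  This package targets
clinical ML researchers and biostatisticians who want an
*interpretable* model over a 40-variable SBT cohort: 19 clinical
variables plus 21 measurements taken at minutes 1, 30, 60 and 90 of the
trial, with a binary outcome (failure = 0 / success = 1).

## The method

**XCSR.**  The model is a population of IF–THEN rules.  A rule's
condition holds one interval predicate per variable,
`int_i = (c_i, s_i)`, matching an input when
`c_i − s_i ≤ x_i < c_i + s_i`; its action is the predicted outcome.
Rules carry a payoff prediction *p*, prediction error *ε*, fitness *F*
(relative accuracy, κ = 1 if ε < ε₀ else α(ε/ε₀)^(−ν)), numerosity and
experience.  Learning alternates explore trials (roulette-wheel action
selection over the prediction array, Widrow–Hoff updates, a niche
genetic algorithm with per-locus crossover and ±U(0, m_i] mutation,
subsumption, roulette deletion under the N-microclassifier budget) with
exploit trials (argmax prediction) whose sliding-window accuracy forms
the learning curve.

**Prob_usage.**  A condition locus whose interval covers a variable's
entire observed range is a *don't care* — the rule ignores that
variable.  Over a stable rule set of `T` rules with `D_i` don't-care
loci on variable *i*,

```
Prob_usage(i) = (T − D_i) / T × 100%
```

is the percentage of rules that actually condition on variable *i*.
The model is built 10 times under different seeds and Prob_usage is
reported as mean ± SD with a descending-mean ranking.

**Statistics.**  Group comparisons use the Mann–Whitney U test
(two-tailed, p < 0.01; exact enumeration for tiny samples, tie- and
continuity-corrected normal approximation otherwise) and rank-based
AUC; the trained model is scored by its prediction-array payoff
difference PA(success) − PA(failure) for ROC analysis.

Because the underlying EMR data are not public, the package includes a
synthetic cohort generator reproducing the published two-group
structure (group-conditional truncated normals and category
frequencies, missing-value injection, 262 → 228 complete-case flow) and
a *planted-rule* mode in which the outcome is a known interval rule —
the ground truth for validating feature recovery.  See
`docs/methods.md` for the full model description and design decisions.

## Worked example

```python
import xcsr_extubation as xe

# emulate the published recruitment: 262 records, 34 incomplete
cohort = xe.exclude_incomplete(xe.generate(xe.GeneratorConfig(seed=1)))
print(len(cohort))                      # 228

# train one model with the published configuration
norm, ranges = xe.normalize(cohort.features)
result = xe.train(norm.to_numpy(float), cohort.outcomes, xe.XCSRParams(seed=1))
print(round(result.final_accuracy, 2))  # 1.0  (in-sample, windowed)

# rule-derived feature importance across 10 seeded builds
report = xe.multi_run_usage(cohort, xe.XCSRParams(), n_runs=10)
print(report.to_frame().head(3)[["rank", "variable", "mean_prob_usage", "sd"]])
```

The same protocol from the shell:

```
xcsr-extubation run-all --seed 1 --output-dir demo_run
```

writes the cohort CSVs, per-seed rule exports (de-normalized
`[low, high)` intervals, `#` for don't-care loci), learning curves, the
usage report, the group-comparison table and ROC points, plus a
manifest.  On the default table-mode cohort the manifest reports
`n_retained: 228` (37 failures / 191 successes for seed 1), per-run
stable-rule counts of 25–106 dominated by success rules (e.g. 32
success / 3 failure in run 1), final windowed training accuracy
0.96–1.0 and in-sample model AUC 0.998–1.0 across the ten runs.  All
model performance figures are in-sample — the protocol defines no
held-out split — and synthetic-cohort rankings reflect the generator,
not real patients.

Every subcommand (`generate`, `train`, `usage`, `stats`, `run-all`)
accepts the same YAML config; the schema with all defaults is in
`docs/example_config.yaml`.

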