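# Methods

This note documents the models, procedures, defaults and design
decisions behind `xcsr_extubation`, and what the synthetic experiments
do and do not show about real clinical data.

## The prediction problem

Patients weaned from mechanical ventilation undergo a spontaneous
breathing trial (SBT); extubation nonetheless fails (respiratory
failure or death within 48 h of tube removal) in roughly 15–20% of
cases.  The package models extubation outcome (failure = 0, success
= 1) from 40 predictors: 19 clinical variables (demographics, APACHE II
and Glasgow coma scores, endotracheal tube size, cuff leak, reason for
ventilation, pre-SBT hemodynamics, maximal inspiratory pressure,
disease histories) and 21 variables sampled during the SBT at minutes
1, 30, 60 and 90 (heart rate, SpO₂, minute ventilation VE, spontaneous
tidal volume, respiratory rate).

The goal is not only prediction but *interpretable feature
importance*: the learner's rule set is read directly to quantify which
variables the model actually conditions on.

## XCSR: the learner

XCSR is an accuracy-based learning classifier system for real-valued
inputs.  A rule is an IF–THEN pair: the condition holds one interval
predicate `int_i = (c_i, s_i)` per input variable, matching `x` when
`c_i − s_i ≤ x_i < c_i + s_i` (half-open at the top); the action is the
predicted outcome bit.  Each rule carries a predicted payoff `p`, a
prediction error `ε`, a fitness `F`, a numerosity (identical copies
folded into one macroclassifier), an experience counter, a GA timestamp
and an action-set size estimate.

One training *trial* presents one patient record:

1. **Match set [M]** — all rules whose condition matches.  If fewer
   than `θ_mna = 2` actions are represented, *covering* creates a rule
   for a missing action: each predicate is, independently with
   probability `P_# = 0.5`, a full-range "don't care" interval;
   otherwise it is centred exactly on the input value with spread drawn
   uniformly from (0, s_r].
2. **Prediction array [PA]** — per action, the fitness-weighted
   (numerosity-weighted) mean of the member rules' payoff predictions.
3. **Action selection** — trials strictly alternate *explore* (roulette
   wheel over the [PA] entries) and *exploit* (argmax; ties break on
   larger fitness mass, then the lower action index).
4. **Reward** — 1000 for a correct prediction, 0 otherwise (single-step
   problem: no discounted next-state term, so the Q-learning backup
   degenerates to the Widrow–Hoff rule on the immediate reward).
5. **Update of the action set [A]** — experience +1; `ε` then `p` move
   toward the observed values at rate β = 0.2, with MAM averaging
   (rate 1/experience) while experience < 1/β; accuracy
   `κ = 1` if `ε < ε₀` else `α (ε/ε₀)^(−ν)`; fitness tracks the
   numerosity-weighted relative accuracy within [A].
6. **Rule discovery** (explore trials only) — action-set subsumption
   (an experienced, accurate, strictly more general rule absorbs the
   rules it contains), then a niche GA: when the numerosity-weighted
   mean time since the last GA in [A] exceeds `θ_GA = 25`, two parents
   are drawn by fitness roulette; offspring exchange interval
   predicates (uniform per-locus crossover, gated at χ = 0.8) and each
   center/spread gene is perturbed by ±U(0, m_i] with probability
   μ = 0.04 (spreads clamped at 0).  Offspring may be subsumed by their
   parents; insertion is followed by roulette deletion (vote =
   action-set size estimate × numerosity, inflated for experienced
   low-fitness rules) whenever the microclassifier count exceeds
   N = 1500.

Training runs 100 shuffled passes over the cohort.  The learning curve
is the fraction correct over a sliding window of the last 50 exploit
trials, recorded per exploit trial.

### Parameter defaults

The published configuration is used verbatim: Epoch 100, N 1500,
β 0.2, α 0.1, ν 0.1, ε₀ 10, θ_GA 25, χ 0.8, μ 0.04, θ_del 20, δ 0.1,
θ_sub 20, P_# 0.5, p_init 10, ε_init 0, F_init 10, θ_mna 2.  Note that
ν = 0.1 and F_init = 10 are unusual for accuracy-based classifier
systems (canonically ν ≈ 5 and F_init ≪ 1); they are kept as published,
and their consequences are discussed under *Limitations*.

Three quantities the published configuration leaves to the user:

* **Reward magnitudes** — 1000 / 0 for correct / incorrect, the
  standard classification payoff scheme and consistent with
  p_init = 10 sitting near the low end of the payoff scale.
* **s_r = 0.5** (covering spread cap) and **m_i = 0.1** (mutation
  step), both on the normalized scale.  Both are configurable and
  logged in every run config.

### Design choices where the procedure was genuinely open

* **Normalization.**  Inputs are min-max scaled to [0, 1] per variable
  over the cohort, so a single `s_r`/`m_i` scale is meaningful across
  variables spanning 0–500+ units.  Ranges are retained; exported
  rules are de-normalized back to measurement units.  A constant
  variable is mapped to 0.5 and flagged.
* **Full-range predicate.**  The covering don't-care interval uses
  spread 0.5 + 10⁻⁶ rather than exactly 0.5: normalization maps the
  observed maximum to exactly 1.0, and with half-open matching a bare
  [0, 1) interval would fail to match maximal records.  The margin is
  far inside the 10⁻⁹ tolerance of don't-care detection.
* **Updates on exploit trials.**  Rule discovery (GA, subsumption) is
  explore-only, but the Widrow–Hoff/fitness update runs on every
  trial.  With 228 records and N = 1500, per-rule experience is the
  scarcest resource (the subsumption and deletion thresholds sit at
  20 updates); updating on both trial types doubles experience flow
  without changing which rules are discovered.
* **Exploration floor.**  Pure payoff-proportional exploration with a
  zero incorrect-reward has an absorbing state: an action whose [PA]
  entry reaches 0 is never sampled again and its estimate can never
  recover.  The training loop therefore floors roulette weights at
  p_init (= 1% of the payoff scale); selection remains effectively
  proportional for any learned payoff difference.
* **Crossover semantics.**  χ is the probability that crossover
  happens at all; when it does, predicates are exchanged per locus
  with probability 0.5 (uniform crossover).  The alternative reading —
  each locus exchanged with probability χ — is available via
  `XCSRParams(crossover="per_locus")`.
* **GA clock.**  The timestamp counter advances once per explore
  trial.

## Synthetic cohorts

The original EMR data are available only on request, so the package
ships a generator reproducing the published two-group structure.

* **Table mode** (default): the outcome is drawn first (failure
  fraction 40/228), then each continuous variable from its outcome
  group's truncated normal (published group mean ± SD) and each
  discrete variable (gender, tube size, ventilation reason, disease
  histories) from the group's published code frequencies.  Defaults
  emulate the recruitment flow: 262 records, exactly 34 with a missing
  value, complete-case filtering to 228.
* **Truncation and calibration.**  Bounds are the pooled mean ± 4 SD
  across groups, clipped at 0 (all quantities here are nonnegative).
  Where truncation is active, the location of the truncated normal is
  calibrated by 1-D root finding so that the *truncated* mean equals
  the published group mean; the published SD serves as the scale
  parameter.  For heavily skewed variables (e.g. 30-min spontaneous
  tidal volume, SD larger than the mean) the achieved SD is smaller
  than published — a coefficient of variation above 1 is unattainable
  for a 0-truncated normal, so both moments cannot be matched
  simultaneously.  Group means converge to the published values
  (within Monte-Carlo error) for every variable.
* **Planted-rule mode**: variables are drawn independently from their
  pooled marginal mixture, and the outcome is a known deterministic
  conjunction of intervals over a chosen feature subset, optionally
  flipped with probability `label_noise`.  `default_planted_rule`
  places each conjunct symmetrically on the pooled marginal spanning
  central mass `f^(1/k)` for `k` conjuncts, so the rule labels ≈ `f`
  (default 0.5) of records positive for any number of planted
  features.  Missing values are injected only into non-planted
  variables, one slot per affected record.

What table mode does *not* model: inter-variable correlation beyond
outcome-group conditioning (real SBT variables are strongly
autocorrelated across time points), measurement error structure,
informative missingness, or survival timing.  Passing tests on these
cohorts therefore demonstrate the correctness and behaviour of the
*method*, not clinical validity on real patients.

## Feature importance: Prob_usage

For a stable rule set of `T` macroclassifiers with `D_i` don't-care
loci on variable `i`,

    Prob_usage(i) = (T − D_i) / T × 100%.

* **Don't care** for an interval predicate is defined as full coverage
  of the variable's normalized observed range: `[c−s, c+s) ⊇ [0, 1)`
  within 10⁻⁹ — the only reading under which a don't-care count is
  computable from interval rules.  A relaxed criterion (coverage
  ≥ 1 − τ) is available for sensitivity analysis (`relax_tau`),
  default off.
* **Stable rules** are selected from the raw population by a
  configurable filter, default experience ≥ 20 (the deletion
  threshold) and matching at least one training record; the published
  rule count (154 of up to 1500) implies some such filter without
  stating one.  Counting is per macroclassifier, matching the "total
  rules" denominator; a numerosity-weighted variant is behind a flag.
* **Protocol**: the model is built 10 times under seeds 1..10;
  Prob_usage is reported as across-run mean ± SD (population SD,
  ddof = 0, since the 10 runs are the entire protocol, not a sample
  from a larger one) and variables are ranked by mean.

## Statistical evaluation

Group comparisons use the Mann–Whitney U test (two-tailed, significance
at p < 0.01, appropriate for the very unequal group sizes).  For both
samples ≤ 8 the p value is an exact enumeration over group assignments
(valid under ties); otherwise the normal approximation with
tie-corrected variance and continuity correction.  AUC is computed by
the rank / pair-counting formulation — identical to the normalized
Mann–Whitney statistic — and reported oriented (max(a, 1−a), direction
recorded), as clinical tables present discriminability.  Summary tables
use the n−1 SD convention.

The trained model's ROC uses per-record scores
PA(success) − PA(failure) from exploit-mode prediction; an absent
prediction-array entry is imputed with the incorrect reward, and
records matched by no rule at all are counted as abstentions.  Model
scores are computed on the training records: the reference protocol
reports training-set performance and describes no held-out split, so
all model AUC/accuracy figures here are *in-sample* and should be read
as such.

## Problem sizes used in tests and the acceptance script

* Training-accuracy check: one 228-record noiseless cohort labelled by
  a 2-variable planted rule, full 100-epoch budget (≈ 15 s).
* Feature-recovery experiment: the full 10-run protocol (seeds 1–10,
  100 epochs each) on a 228-record noiseless cohort with the 6-variable
  planted set (≈ 2.5 min).
* Generator convergence: 40 000 records at failure fraction 0.5
  (≈ 20 000 per group), group means within 3 standard errors.

## Known limitations

* **Differential generalization is slow under the published
  configuration.**  In 40 dimensions, covering (P_# = 0.5) produces
  rules that match essentially only their creating record, so the
  population operates in a memorization regime: median rule experience
  stays near 1, the experience-gated mechanisms (subsumption,
  deletion-vote inflation) rarely engage, and numerosity never
  concentrates.  Training accuracy on separable problems still reaches
  ≈ 100% (the prediction array is driven by per-record niches), but
  the *structural* signal — planted variables staying constrained
  while irrelevant loci drift to full range — consolidates far more
  slowly than the 100-epoch budget: the planted/non-planted mean
  Prob_usage gap is ≈ 1 point at 100 epochs and ≈ 13 points at 600
  epochs.  This is insensitive to the accuracy exponent ν (0.1 vs the
  canonical 5), the covering spread cap s_r, the mutation step m_i and
  the stable-rule filter.  Consequently the 6-variable recovery
  experiment does not reproduce a clean top-6 ranking at the published
  training budget, and the corresponding acceptance test is expected
  to fail until a faster consolidation mechanism (e.g. tournament
  selection or condensation phases) is added — deliberately out of
  scope here, since the algorithm follows the published description.
* The ν = 0.1 accuracy exponent makes the fitness landscape nearly
  flat above ε₀, weakening selection against overgeneral rules; it is
  retained as published.
* Prob_usage is a *syntactic* importance measure: an interval covering
  99% of a variable's range counts as "using" the variable under the
  strict criterion (see `relax_tau`).
* Synthetic cohorts carry no inter-variable correlation; real SBT
  time series would make several variables mutually redundant, which
  Prob_usage cannot disentangle.
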