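# Methods

## The choice process and its two analyses

A best-worst scaling task shows a respondent k items from a catalogue
of J and asks for the most and the least important. We model the two
picks sequentially: the best item b is drawn from the task set S with
conditional-logit probability exp(u_b)/Σ_{j∈S} exp(u_j); the worst
item w is then drawn from S∖{b} with the utilities negated,
exp(−u_w)/Σ_{j∈S∖{b}} exp(−u_j). The best pick is unconditional; the
worst pick is conditioned on the best. Both stages share one utility
vector u per (sub)sample, so a fit yields one estimate per item.

Two estimators are implemented.

1. **Count scoring** (`bwspref.counts`). s_j = (B_j − W_j)/(r·n),
   where r is the per-respondent appearance count of each item — the
   design must be frequency balanced for this denominator to make
   sense, and `mean_bw_scores` refuses unbalanced designs. Because
   every task yields one best and one worst, Σ_j (B_j − W_j) = 0 and
   scores sum to zero exactly. s_j is also the mean of per-respondent
   scores b_ij ∈ [−1, 1], which give SE, one-sample t (n−1 df,
   two-sided) and Welch two-sample tests between strata (pooled
   variance available via `pooled=True`; the choice does not affect
   any packaged reproduction).

2. **Sequential conditional logit** (`bwspref.clogit`). The stacked
   likelihood over best groups (k alternatives, weight +1) and worst
   groups (k−1 alternatives, weight −1) is maximized in the J−1
   effects-coded coefficients. The likelihood is concave; we use
   damped Newton with analytic gradient and observed information,
   declaring convergence at gradient max-norm < 1e−8 or relative
   log-likelihood change < 1e−10 (the survey-scale problems here
   converge in ~6 steps). The covariance is the inverse observed
   information; the omitted item's coefficient is −Σβ with SE
   √(1ᵀV1). Standard errors treat the two stages and the 16 tasks per
   respondent as independent observations — the conventional plain
   conditional-logit treatment for this design; no respondent
   clustering is applied.

### What the two rankings can and cannot agree on

Count scores are not a monotone transform of utilities unless every
item faces every other equally often. Under unequal pairwise
co-occurrence an item that happens to meet weaker competitors gets a
higher expected score. Exact expected-score computation at the
packaged utilities shows the two lowest-utility sectors (legislature,
public administration) and the third-lowest separated by only ~0.02
expected-score units at the survey design, so the two analyses can
durably disagree about the very bottom of the ranking — as the
published tables themselves do (the count table ranks legislature
last; the logit ranks public administration last). Tests therefore
assert rank agreement where it is identifiable (the top item; full
agreement under symmetric exposure) rather than blanket agreement.

## Design generation

`generate_design(J, k, T, seed)` requires T·k divisible by J and
builds tasks in two phases: a greedy fill that always places the items
with the most appearances still owed (at most k items can be owed as
many appearances as there are tasks left, so exact balance is always
reached), preferring low co-occurrence with the partially built task,
with a seeded random tie-break; then a first-improvement pairwise swap
descent that strictly reduces (co-occurrence range, sum of squared
co-occurrences) until no swap helps. The result is deterministic given
the seed. For the survey shape (16, 4, 16) the 96 co-occurrence slots
cannot cover the 120 item pairs, so some pairs never meet; the
descent typically ends at range 2. `validate_design` reports, and
never enforces, the balance diagnostics.

The instrument's actual 16 task compositions were never published; any
frequency-balanced design is statistically equivalent for everything
this package computes, which is why the design module ships a
generator rather than a transcription.

## The simulator and what passing tests show

`simulate_responses` draws each respondent's utilities as the stratum
mean (centered to sum to zero, mirroring effects-coding
identification) plus optional i.i.d. normal heterogeneity with
standard deviation σ, then samples best and worst by the closed-form
softmax probabilities above — the exact model the logit fits, and the
model whose count scores the scoring module expects. Each respondent
consumes an independent child seed stream, so results are reproducible
and insensitive to stratum ordering.

Defaults mirror the study conditions: J = 16 sectors, 16 tasks of 4,
432 respondents (217 urban / 215 rural), σ = 0 for estimator tests
(the fitted model is a fixed-coefficient logit, so σ = 0 is the
model-faithful case; σ > 0 scenarios are robustness checks only, with
no study-anchored value). True utilities for recovery experiments are
the centered published estimates.

The simulator deliberately omits features of real stated-preference
data: item-order and fatigue effects, covariate-dependent
preferences, inattention, and any deviation from the sequential-logit
decision rule. Passing recovery tests therefore show the estimator is
correct *for its model*, not that the model is correct for Ugandan
households.

## Budget alignment

"Anchored at zero" is implemented as d_j = s_j − min_k s_k, giving the
minimum-score sector exactly 0% preference share; shares are
100·d_j/Σd and sum to 100 by construction. An `anchor_epsilon` option
anchors at min−ε instead, for users who prefer a nonzero floor — the
anchoring convention is the one genuinely open choice in this
transform, and the default is the literal reading. The transform is
invariant to scaling and shifting of scores and preserves their order,
so preference ranks equal count-score ranks.

Budget shares are inputs, never recomputed. The packaged figures are
the nine sectors whose 2017–18 shares were quoted (health 6.4, water
and environment 4.6, education 21.3, agriculture 6.1, works and
transport 22.1, social development 1.5, security 10, justice/law/
order 7.2, ICT 0.3) plus the quoted ranks; the remaining seven
sectors' shares were not published, so rank-based comparison uses the
supplied ranks and computed-rank comparison requires a complete share
vector.

## Numerical and testing choices

- Display rounding is banker's 3 dp, but all comparisons against
  published score values use absolute tolerance 0.001: a few printed
  third decimals are truncated rather than rounded (e.g. health
  1372/1728 = 0.7940 printed as 0.793), and 0.001 absorbs the
  publisher's convention without replicating it.
- Published-table reproductions use exact integer tallies, so they are
  deterministic and sub-second.
- Ranks break ties by catalogue order, making every ranking a
  deterministic permutation of 1..J.
- Likelihood verification compares the vectorized implementation with
  a pure-python enumeration of P(best)·P(worst|best) on random small
  instances (J ≤ 5, k = 3) at 1e−10.
- Parameter recovery runs 20 survey-shaped replicates (n = 432,
  σ = 0): per-item mean estimates within 3 Monte-Carlo standard
  errors of truth and the true top sector recovered in ≥ 19/20 seeds.
  With 16 items, the max-deviation statistic occasionally exceeds 3
  MC SEs by chance under reseeding; the suite's seeds are fixed.
- Monte-Carlo regression bounds for the count-ranking identification
  test were frozen from a 400-replicate run at the study conditions
  (top-4 set always recovered; bottom-2 set in 78% of replicates —
  see the co-occurrence discussion above): 99.9% binomial lower
  bounds of 96/100 and 65/100.
- Type-I calibration pools per-sector one-sample tests over 200
  equal-utility replicates; a 1000-replicate run estimates the true
  rejection rate at 0.051 (SE 0.002). The per-replicate rejection
  counts are very slightly over-dispersed relative to binomial (sector
  scores are negatively correlated within a replicate), so the pooled
  binomial bound is mildly anti-conservative across reseeds.
- Degenerate inputs: k = 2 worst groups are singletons and contribute
  zero likelihood; all-equal scores make preference shares undefined
  (error); strata need ≥ 2 respondents for a variance; items never or
  always chosen trigger a separation warning and a flagged fit.

## Known limitations

- Reproducing the published logit estimates (e.g. health 3.027)
  requires the study's raw choice data, which was deposited in a
  binary statistical-package format this package does not read; the
  packaged estimates serve as reference values and simulation truth.
  Everything count-based is reproduced exactly from printed tallies.
- No respondent-level clustering or mixed-logit heterogeneity in the
  estimator; σ > 0 simulations quantify robustness, not a fitted
  model.
- No D-efficient or Bayesian design optimization; the generator
  targets frequency balance and co-occurrence spread only.
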