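# Methods

## The sharing game

A fixed, connected, simple undirected network links `n` agents, each
endowed with a positive integer token income. Rounds are synchronous:
every agent observes the round-start incomes of itself and its
neighbors, decides whether to give, how much, and to whom; all
transfers are then applied at once. Because amounts are capped at the
giver's round-start balance and transfers are settled jointly, no
balance ever goes negative and the token total is conserved exactly
(integer equality, asserted in tests on every trial). The game ends at
the first round in which nobody gives, or after a hard cap of 10 rounds
(`max_rounds`), mirroring laboratory practice where an idealized
"stop when nobody gives" rule needs a compulsory time limit.

## Decision model

Giving is a two-part (hurdle) process driven by four covariates, all
computed from round-start incomes:

- `X` own income (tokens);
- `R` normalized income rank among self + neighbors, low to high,
  average ranks under ties, in (0, 1];
- `L` local inequality, the population Gini of self + neighbor incomes,
  in [0, 1);
- `K` degree (constant over time).

Part 1 (participation): give with probability
`logistic(a_p + C_X X + C_R R + C_L L + C_K K)`.
Part 2 (magnitude): propose `round(logistic(a_m + C'_X X + C'_R R +
C'_L L + C'_K K) · X)` tokens, clamped to the current balance. A
proposal that rounds to zero counts as not giving, so the recorded give
indicator always agrees with a positive amount.

The logistic form for both parts is a deliberate design choice: it
makes the simulator exactly conjugate to the logistic participation
model used in inference, so parameter-recovery tests have a
well-defined ground truth. The amount part, by contrast, is
*deliberately not* the zero-truncated Poisson used for inference —
fitted amount coefficients are descriptive, not recoverable
parameters (see "Recovery harness" below).

Recipient choice discretizes a Beta(β1, β2) preference over poverty
rank: neighbors sorted poorest to richest (ties broken by node id) own
`m` equal consecutive bins of [0, 1), the poorest owning [0, 1/m); each
token lands independently in the bin of a fresh Beta draw. Under
β1 = β2 = 1 this is exactly uniform over neighbors; left-skewed shapes
(β1 < 1 ≤ β2, e.g. 0.21/1.03) concentrate tokens on the poorest; the
per-token rule covers single-recipient and even-split behavior as
limiting cases, and allocation frequencies converge to the discretized
Beta bin masses (chi-square checked at 10^5 tokens).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `a_p` | −1.05 | participation intercept |
| `c_l` | 4.0 | participation response to local inequality |
| `c_x`, `c_r`, `c_k` | 0 | inert by default; free knobs |
| `a_m` | −2.75 | amount intercept (logistic fraction of income) |
| `c_l_amt` | 2.0 | amount response to local inequality |
| `beta1`, `beta2` | 1.0, 1.7 | left-skewed recipient preference |
| `max_rounds` | 10 | compulsory stop |

Local inequality is the only active covariate by default because it is
the mechanism of interest: the model's qualitative prediction — only
treatments that make local income contrasts salient reduce global
inequality — flows through `L`. The two intercepts were calibrated once
against first-round behavior: with these values, across the five
standard treatments (200 seeded trials), 50.0% of agents donate in
round 1 and the mean fraction of income given in round 1 is 5.2%,
decaying by round 10 to 38% and 3.0% as redistribution compresses local
inequality. The calibration targeted only the round-1 levels; the decay
is emergent. These values were frozen before any acceptance checks were
run and are not tuned to them.

## Network treatments

- Incomes: `n` evenly spaced integers from `lo` to `hi`
  (`lo + i(hi−lo)/(n−1)` rounded; endpoints exact). Standard profile:
  n = 25, 10–200 tokens, population Gini 0.3131 (closed form for an
  evenly spaced profile: `d(n²−1)/(6nμ)` with gap `d` and mean `μ`).
- Lattices: 4-regular ring (each node tied to two neighbors per side),
  50 edges at n = 25. Homophilous placement lays sorted incomes around
  the circle (provably minimal neighbor contrast among circular
  arrangements; brute-force-verified at n = 6); heterophilous placement
  interleaves the sorted list end-to-end (low, high, next-low,
  next-high, …), a deterministic arrangement that maximizes local
  contrast.
- Scale-free: preferential attachment from a seed clique with
  attachment count m ∈ {1, 2} (largest fitting the edge budget), then
  preferential top-up edges to **exactly** the lattice edge count
  (2n for k = 4), so density is matched while the degree distribution
  stays right-skewed. Incomes are rank-matched to degree (positive or
  negative), ties broken by node id, which extremizes the
  degree–income Spearman correlation among all placements.
- Full: all pairs, 300 edges at n = 25.

The income multiset is identical across all five treatments; only
placement differs. Session sizes of 18–25 reuse the same generators.

## Synthetic experiment

`generate_sessions` emulates the within-subject laboratory design:
each session draws fresh scale-free networks, a random order of the
five treatments, and per-subject intercept offsets
`~ Normal(0, σ_subj)` applied to the participation part only — the
simplest mechanism that induces the within-subject correlation the
clustered-error analyses assume. σ_subj defaults to 0.3; it is a
synthetic knob, not an estimate of real heterogeneity. Session *s*
derives all randomness from `seed + s`. `drop_trials` removes trials
uniformly at random, emulating the loss of trials to software failure
(35 run → 31 analyzable in the standard configuration).

What the generator does **not** emulate: decision timing, dropout
within a round, learning or strategy shifts across trials, and any
amount process other than the logistic-fraction rule. Passing
recovery tests therefore certifies the inference code on data whose
generating process is known, not the behavioral realism of that
process.

## Inference

- **Hurdle regression.** Part 1: logistic regression of the give
  indicator on (X, R, L, K). Part 2: zero-truncated Poisson with log
  link on the positive token amounts (tokens are integers, making a
  truncated count family the natural magnitude model), fitted on
  giver-rounds only, warm-started from an untruncated Poisson. Both
  parts use cluster-robust (sandwich) covariance grouped by subject
  (session × subject when sessions are pooled). Covariates without
  variance in a subset (degree in a regular lattice) are dropped and
  reported, mirroring the treatment-wise analysis where K is undefined
  for lattices.
- **Beta fit.** Recipient positions are the recipient's income rank
  among the giver's neighbors at round start, mapped to bin midpoints
  `(rank − ½)/m` so the Beta support stays open. Shapes are estimated
  by numerical MLE with location/scale pinned to (0, 1).
- **Wilcoxon signed-rank.** W = sum of ranks of positive differences
  (end − initial), zero differences dropped. For n ≤ 25 the null
  distribution is computed exactly by a subset-sum dynamic program over
  doubled midranks — identical to enumerating all 2^n sign patterns and
  valid under ties; above that, a normal approximation with tie and
  continuity corrections. Default sidedness is one-sided "end <
  initial". Seven uniformly improved sessions give W = 0,
  p = 1/128 ≈ 0.0078. No multiple-testing correction is applied across
  the five treatments (raw per-treatment tests are reported).
- **Reverse redistribution.** An event is reverse when the recipient's
  round-start income is at least the giver's. The reciprocity model is
  the same hurdle applied to the reverse-donation indicator/amount with
  tokens received in the previous round as the sole covariate.

### Recovery harness

The parameter-recovery check fits the hurdle on synthetic data from
known parameters (7 sessions × 25 subjects, σ_subj = 0.3, 20 seeded
replicates) and asks that the participation-part coefficients be
covered by estimate ± 2 cluster-robust SEs in ≥ 90% of
(coefficient, replicate) pairs. Two numerical subtleties are by
design:

1. The harness ground truth uses a flat amount part at the calibrated
   giving intensity (log-odds −2.2), because with income-dependent
   amounts the integer token floor can censor the give indicator for
   poor agents, in which case the generating participation coefficient
   is no longer the estimand of the observed indicator.
2. A pooled marginal logit on dynamic data with subject random
   intercepts is mildly attenuated: generous subjects deplete their own
   incomes, correlating the omitted intercept with later-round rank.
   The effect is about one SE on the rank coefficient at σ_subj = 0.3
   (σ_subj = 0 runs are unbiased) and is a property of the estimator on
   such data, not an implementation artifact; coverage is therefore
   assessed pooled across coefficients.

Amount-part coefficients are not coverage-checked: the generator's
logistic-fraction rule and the truncated-count inference model are
different parameterizations on purpose (the inference side follows the
field's convention for integer outcomes), so no numeric equality is
defined between them.

## Numerical choices

- Gini: population form (no n/(n−1) correction), computed by the
  sorted-order identity; all-zero vectors are an error. This makes the
  local Gini of a fully connected neighborhood equal the global Gini
  exactly.
- Ranks: average under ties everywhere (R, recipient positions,
  Wilcoxon).
- Seeds: one base seed per batch/experiment; replicate r uses
  `base_seed + r`; within a trial, draws are consumed in fixed agent-id
  order, so every output is bit-reproducible given its seed.
- Problem sizes in tests and the acceptance script (100-replicate
  batches, 20-replicate recovery, 10^5-token allocation checks) were
  chosen as the smallest sizes at which the checked quantities are
  stable to well under their tolerances.

## Known limitations

- The simulator is a stylized model: no learning, no rewiring, no
  transaction costs, no timing effects.
- The amount model's integer rounding creates a giving floor at very
  low incomes (a proposal under half a token is no gift); analyses of
  very poor agents' participation inherit this discreteness.
- Scale-free generation fixes one of many possible constrained
  preferential-attachment variants; degree sequences vary across seeds,
  so scale-free treatment results are conditional on the drawn network
  (the batch runner holds the network fixed across replicates).
- The reverse-redistribution share in synthetic data (≈ 38% under
  default parameters) is substantially higher than is typical of human
  data, because the per-token Beta allocation always spreads some
  tokens upward; treat it as a property of the allocation rule, not a
  behavioral prediction.
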