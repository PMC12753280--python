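# Methods

## Model

The state is a single probability *p* that treatment A is superior to
treatment B (a strictly binary hypothesis space; no third option, no
effect-size uncertainty). Evidence arrives as a likelihood ratio
LR = P(evidence | A superior) / P(evidence | B superior), and the update is
the odds-form Bayes rule with an exponent applied to the likelihood ratio:

    posterior_odds = prior_odds × LR^w

Confirmation bias is the asymmetry of the exponent: w = 1 for confirming
evidence, w = w_d ≤ 1 for disconfirming evidence. Because the exponent
multiplies the log-likelihood-ratio, w_d = 0.5 is exactly "contrary
evidence counts half": on an all-disconfirming stream, 2k biased trials
move the belief precisely as far as k unbiased trials (the time-dilation
property, asserted in the tests).

Classification is sequential and path-dependent. Each trial is judged
against the belief held *before* that trial's update: the agent favours A
when p ≥ threshold (default 0.5) and B otherwise; evidence favouring the
non-favoured side is disconfirming; LR = 1 is neutral. Two consequences
matter:

* **Tie rule.** Belief exactly at the threshold counts as favouring A, so
  B-favouring evidence at equipoise is disconfirming. This is what makes a
  neutral starting agent's *first* contrary trial biased and all later ones
  confirming, and it is why the neutral agent's biased endpoint sits
  slightly *above* (in belief-in-A terms, i.e. the reported percentage is
  slightly higher than) its unbiased endpoint.
* **Threshold crossing.** Once belief crosses the threshold, the same
  evidence flips from disconfirming to confirming, so a biased trajectory
  is not a closed form in general; it must be simulated step by step.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| prior | initial P(A superior) | 0.90 / 0.50 / 0.10 | the three canonical archetypes: Loyalist, Neutral, Advocate |
| n_trials | length of the evidence stream | 10 | the canonical constant-effect experiment |
| LR | per-trial likelihood ratio | 0.72 / 0.678 / 0.80 per archetype | closed-form calibration of each archetype's published unbiased endpoint (25%, 2.0%, 1.2%), rounded to ≤ 3 significant figures |
| w_disconfirming | bias exponent on contrary evidence | 0.5 | a moderate bias: contrary evidence counts half |
| threshold | belief level separating "favours A" from "favours B" | 0.5 | symmetric two-option choice |
| clamp | probability floor/ceiling | 1e−12 | keeps odds finite at extreme priors |

### Why per-archetype likelihood ratios

The three published unbiased endpoints are mutually inconsistent under any
single constant LR: inverting (prior, final, 10) gives implied LRs of
about 0.7192, 0.6776 and 0.8014. Rather than silently picking one value,
the package treats the LR as a free, calibratable parameter, ships the
reference scenario with per-archetype constants, and exposes the
inconsistency through `calibration.implied_lr_report` (the reference rows
flag inconsistent at tolerance 0.01). One knock-on effect: with the
Neutral-calibrated LR of 0.678 the model places the Neutral biased endpoint
at ≈ 2.4%, not the published 2.3%; the reproduction reports the computed
value, and whether the original figure reflects rounding or a different LR
cannot be determined from endpoints alone.

## Evidence generators

* **fixed** — n identical likelihood ratios; the canonical experiment uses
  LR < 1 throughout (all evidence favours B).
* **mixed** — n_A trials at LR = m > 1 and n_B at 1/m, shuffled
  deterministically under a seed. Reciprocal magnitudes make the evidence
  strength symmetric, so the unbiased final equals the prior whenever
  n_A = n_B — which isolates order effects: under bias, different
  orderings of the same mixed multiset reach different finals.
* **binomial** — a generative extension: each trial draws success counts
  for both arms from binomials under the true hypothesis (point hypotheses
  fully specify both arms' rates), and the LR is the ratio of the joint
  binomial point masses, computed in log space via `scipy.stats.binom`.
  This emulates sampling noise in trial results; it does not emulate
  heterogeneous trial quality, publication bias, non-binary outcomes or
  priors over effect sizes, so passing tests say nothing about those
  features of real evidence streams.

## Inverse problems and numerics

* `calibrate_constant_lr` is the exact algebraic inverse
  LR = (odds(final)/odds(prior))^(1/n).
* `solve_bias_factor` bisects on w ∈ [0, 1], evaluating every iterate by a
  full forward simulation so threshold crossings are honoured. The final
  belief is monotone in w on one-directional streams, which guarantees the
  bracket; bisection runs to bracket width < 1e−13 (≤ 200 iterations)
  rather than stopping at a belief tolerance, because final(w) can be
  nearly flat where beliefs saturate. If the observed endpoint lies outside
  the range attainable over w ∈ [0, 1], the error reports that range.
* All updating accumulates in log-odds; a run's state is carried in
  log-odds across trials, so an unbiased trajectory's endpoint is
  bit-identical to logistic(log-odds(prior) + Σ log LR). Zero-increment
  updates (LR = 1, or w = 0) return the belief unchanged exactly instead
  of round-tripping through the logistic.
* Reported endpoints use half-away-from-zero rounding with mixed
  precision: integers at ≥ 10%, one decimal below 10%. Trajectory tables
  keep full precision.

## Design choices that were genuinely open

* **Tie at the threshold counts as favouring A.** The alternative (ties
  are unclassified or confirming) makes the neutral agent's biased and
  unbiased trajectories identical, contradicting the reference behaviour
  where they differ slightly.
* **Bias exponents are capped at 1.** Over-weighting of confirming
  evidence (w > 1) is representable in principle but excluded; the policy
  type enforces [0, 1].
* **The binomial mode is an extension, not the canonical experiment.**
  The reference scenario uses fixed LRs; the generative mode exists for
  stochastic sensitivity work and records its seed in all outputs.

## Problem sizes

Every experiment in the tests and the acceptance script is desk-scale:
10-trial streams, ≤ 1000 simulated binomial trials for the stochastic
sanity checks, ≤ 50 permutations in the order experiment. The full suite
runs in seconds on one CPU.

## Limitations

Two hypotheses only; no debiasing dynamics (peer review, registry
feedback); no anchoring/framing/self-serving biases; no joint fitting of
(LR, w) from full trajectories — the inverse problems each take the other
parameter as known. The simulation makes no claim about the clinical
superiority of either arthroplasty.
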