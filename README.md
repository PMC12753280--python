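# beliefbias

Sequential Bayesian belief updating under confirmation bias, for
two-treatment comparative decisions.

Surgeons (and clinicians generally) who see the same stream of trial
evidence can end up with very different convictions about which of two
treatments is superior. `beliefbias` simulates this as odds-form Bayesian
updating with an optional confirmation-bias distortion, using the choice
between anatomic (aTSA) and reverse (rTSA) total shoulder arthroplasty as
its motivating example. It is aimed at clinical-decision researchers and
educators who want a quantitative, reproducible sandbox for belief dynamics
— not at adjudicating which procedure is better.

## The model

An agent holds a probability *p* that treatment A is superior. Each trial
contributes a likelihood ratio

```
LR = P(evidence | A superior) / P(evidence | B superior)
```

so LR > 1 favours A and LR < 1 favours B. The unbiased update is the
odds-form Bayes rule; confirmation bias raises the LR of *disconfirming*
evidence to an exponent w ∈ [0, 1]:

```
posterior_odds = prior_odds × LR^w        (odds = p / (1 − p))
```

with w = 1 for confirming evidence. Evidence is classified against the
belief held *before* the update: an agent at or above the 50% threshold
favours A, below it favours B, and evidence is disconfirming when it points
at the non-favoured treatment. All arithmetic runs in log-odds space with
probabilities clamped to [1e−12, 1 − 1e−12].

The package also solves the inverse problems: recovering the constant
per-trial LR implied by a (prior, final, n) triple in closed form, and
recovering the bias exponent w from a biased endpoint by bisection over
forward simulations.

## Worked example

Three archetypal surgeons — an aTSA Loyalist (prior 0.90), a Neutral
Thinker (0.50) and an rTSA Advocate (0.10) — each review ten trials of
constant, modestly B-favouring evidence, once without bias and once with
disconfirming evidence down-weighted at w = 0.5:

```python
>>> import beliefbias as bb
>>> for r in bb.archetype_comparison():
...     print(f"{r.archetype:16s} {r.condition:9s} {bb.format_percent(r.final_belief)}")
aTSA Loyalist    unbiased  25%
aTSA Loyalist    biased    64%
Neutral Thinker  unbiased  2.0%
Neutral Thinker  biased    2.4%
rTSA Advocate    unbiased  1.2%
rTSA Advocate    biased    1.2%
```

Reading the numbers: without bias every archetype converges toward low
belief in A, but bias leaves the Loyalist at 64% instead of 25% — a
39-point gap from down-weighting ten contrary trials. The Neutral Thinker
crosses the 50% threshold on trial one, after which all further B-favouring
evidence *confirms* the new lean, so bias barely matters; for the Advocate
every trial confirms from the start and bias never triggers at all.

Each archetype's constant LR (0.72, 0.678, 0.80) is calibrated in closed
form from its unbiased endpoint. The three implied LRs are mutually
inconsistent — no single constant LR reproduces all endpoints at once —
and the package surfaces that as a diagnostic:

```python
>>> report = bb.implied_lr_report([("Loyalist", 0.90, 0.25, 10),
...                                ("Neutral", 0.50, 0.020, 10),
...                                ("Advocate", 0.10, 0.012, 10)])
>>> [round(r.implied_lr, 4) for r in report.results], report.consistent_flag
([0.7192, 0.6776, 0.8014], False)
```

The same experiment is available from the shell, along with the inverse
problems, parameter sweeps and an evidence-order sensitivity experiment:

```
beliefbias reproduce --out out/
beliefbias calibrate --prior 0.9 --final 0.25 --n 10
beliefbias solve-w --prior 0.9 --lr 0.72 --n 10 --final 0.635226
beliefbias run configs/reference_scenario.yaml
beliefbias order-experiment --n-permutations 50 --format json
```

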