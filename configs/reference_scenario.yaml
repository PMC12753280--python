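# Canonical three-archetype comparison: ten constant B-favouring trials,
# disconfirming evidence down-weighted with exponent 0.5 in the biased
# condition.  Per-archetype likelihood ratios are calibrated to each
# archetype's published unbiased endpoint (see docs/methods.md).
name: archetype-comparison
archetypes:
  - {name: aTSA Loyalist, prior: 0.90, lr: 0.72}
  - {name: Neutral Thinker, prior: 0.50, lr: 0.678}
  - {name: rTSA Advocate, prior: 0.10, lr: 0.80}
stream:
  mode: fixed
  n_trials: 10
  lr: 0.72   # fallback for archetypes without an override
bias:
  w_confirming: 1.0
  w_disconfirming: 0.5
  threshold: 0.5
seed: 0
output_dir: out
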