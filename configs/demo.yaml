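# Demo study configuration for `mrkit run`
# (synthetic hip-OA-like cohort; completes in well under five minutes)
seed: 20201007
n_individuals: 20000
theta: 0.3001    # log-odds per SD exposure (OR 1.35)
prevalence: 0.032
mediator_theta: 0.2
mediator_effect: 0.1
pleiotropy: 0.0
n_mediator_snps: 63
effects_model: auto
power:
  r2_xz: 0.02
  K: 0.032
  or_alt: 1.35
  alpha: 0.05
output_dir: results/run
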