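# Four-arm study whose combination arm carries a strong positive interaction
# (iota = 0.3: the drug triples the radiation kill), for exercising the
# synergistic branch of the Bliss classification.
seed: 1
control_arm: control
growth:
  arms:
    - {name: control, n: 12, follow_up: 44}
    - {name: EBRT, n: 8, follow_up: 44, surviving_fraction: 0.25}
    - {name: Gem low, n: 10, follow_up: 44, gem_multiplier: -0.36}
    - {name: EBRT + Gem low, n: 8, follow_up: 44, surviving_fraction: 0.25,
       gem_multiplier: -0.36, interaction: 0.3}
  noise_cv: 0.15
combinations:
  EBRT + Gem low: [EBRT, Gem low]
interaction_tolerance: 0.05
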