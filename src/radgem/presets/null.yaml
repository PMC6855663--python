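# Null study: four arms with identical (neutral) kinetics. Useful for
# type-I-error checks of the statistics stage — no arm should differ from
# control beyond the nominal alpha.
seed: 1
control_arm: control
growth:
  arms:
    - {name: control, n: 6, follow_up: 16}
    - {name: arm A, n: 6, follow_up: 16}
    - {name: arm B, n: 6, follow_up: 16}
    - {name: arm C, n: 6, follow_up: 16}
  noise_cv: 0.15
combinations: {}
interaction_tolerance: 0.05
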