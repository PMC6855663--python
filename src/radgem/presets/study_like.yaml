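# Seven-arm combination-therapy study emulation: radionuclide therapy (Lu),
# external beam radiotherapy (EBRT), gemcitabine at two dose levels, their
# combinations and an untreated control. Effect sizes are calibrated so the
# noiseless model reproduces the qualitative monotherapy patterns: a gem-arm
# RTV ratio-to-control plateauing near 0.5 after the dosing window, an EBRT
# nadir of ~0.6 around day 13, and a low-uptake radionuclide arm that tracks
# the control.
seed: 1
control_arm: control
growth:
  arms:
    - {name: control, n: 12, follow_up: 30}
    - {name: Lu, n: 5, follow_up: 16, surviving_fraction: 0.98}
    - {name: Gem high, n: 5, follow_up: 16, gem_multiplier: -0.55}
    - {name: Lu + Gem high, n: 5, follow_up: 16, surviving_fraction: 0.98,
       gem_multiplier: -0.55, weight_loss_hazard: 0.01}
    - {name: EBRT, n: 5, follow_up: 44, surviving_fraction: 0.25}
    - {name: Gem low, n: 10, follow_up: 44, gem_multiplier: -0.36}
    - {name: EBRT + Gem low, n: 6, follow_up: 58, surviving_fraction: 0.25,
       gem_multiplier: -0.36}
  baseline_mean_mm3: 570.0
  baseline_sd_mm3: 406.0
  growth_rate: 0.042
  regression_rate: 0.12
  gem_window: [0.0, 13.0]
  noise_cv: 0.15
  kill_volume_cap_mm3: 2500.0
combinations:
  Lu + Gem high: [Lu, Gem high]
  EBRT + Gem low: [EBRT, Gem low]
interaction_tolerance: 0.05
dosimetry:
  # synthetic mono-exponential washout of a low-uptake tumour tracer
  simulate: {c0: 0.0175, lambda_per_h: 0.0115,
             times_h: [1, 4, 24, 48, 96, 168], noise_cv: 0.05}
  energy_per_decay_kev: 147.9
  absorbed_fraction: 1.0
histology:
  size: [256, 256]
  pairs:
    - {group: control, ki67_positive_fraction: 0.64,
       mt_collagen_fraction: 0.03, necrotic_fraction: 0.2}
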