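# Passive membrane, leak and baseline-calibration settings.
#
# cm (µF/cm²) and ra (Ω·cm) are uniform; rm (kΩ·cm²) follows a logistic
# profile of dendritic path distance from rm_soma at the soma to rm_tip at
# the most distal dendritic tip (soma and axon take rm_soma).
#
# `calibration` holds the recorded baseline scaling of the somatic/axonal
# sodium and delayed-rectifier densities (within ±30% of the table values)
# used to match the control F-I features before any modulation experiment.
passive:
  cm: 1.5
  ra: 68.0
  rm_soma: 36.0
  rm_tip: 5.4
  e_leak: -70.0
  v_init: -70.0
spine_correction:
  basal_onset: 20.0
  apical_onset: 100.0
# recorded baseline calibration (somatic/axonal rules only)
calibration:
  Na: 1.0
  Na_x: 1.0
  K_V: 1.05
protocols:
  fi:
    max_amplitude_pA: 600
    increment_pA: 50
    duration_ms: 1000
  dt_ms: 0.025
  record_dt_ms: 0.05
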