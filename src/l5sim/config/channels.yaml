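# Declarative summary of the channel library (generated from
# l5sim.channels.export_channel_config; kept in sync by a test).
temperature_C: 32.0
q10: 2.3
reversal_potentials_mV:
  Na: 60.0
  K: -90.0
  H: -45.0
  Ca: 140.0
calcium_pool:
  resting_mM: 0.0001
  decay_tau_ms: 130.0
  shell_depth_um: 0.45
bk:
  vhalf_ref_mV: 20.0
  ca_ref_mM: 0.001
  shift_mV_per_decade: 55.0
  slope_mV: 28.0
  tau_ms: 1.0
channels:
  Na:
    reversal_mV: 60.0
    temperature_factor: 2.116192
    gates:
    - label: m
      exponent: 3
      calcium_dependent: false
    - label: h
      exponent: 1
      calcium_dependent: false
  Na_x:
    reversal_mV: 60.0
    temperature_factor: 2.116192
    gates:
    - label: m
      exponent: 3
      calcium_dependent: false
    - label: h
      exponent: 1
      calcium_dependent: false
  Na_P:
    reversal_mV: 60.0
    temperature_factor: 1.0
    gates:
    - label: m
      exponent: 1
      calcium_dependent: false
  K_V:
    reversal_mV: -90.0
    temperature_factor: 2.116192
    gates:
    - label: n
      exponent: 1
      calcium_dependent: false
  K_M:
    reversal_mV: -90.0
    temperature_factor: 2.116192
    gates:
    - label: n
      exponent: 1
      calcium_dependent: false
  K_AP:
    reversal_mV: -90.0
    temperature_factor: 1.0
    gates:
    - label: n
      exponent: 4
      calcium_dependent: false
    - label: l
      exponent: 1
      calcium_dependent: false
  K_AD:
    reversal_mV: -90.0
    temperature_factor: 1.0
    gates:
    - label: n
      exponent: 4
      calcium_dependent: false
    - label: l
      exponent: 1
      calcium_dependent: false
  K_BK:
    reversal_mV: -90.0
    temperature_factor: 1.0
    gates:
    - label: m
      exponent: 1
      calcium_dependent: true
  Ca_HVA:
    reversal_mV: 140.0
    temperature_factor: 2.116192
    gates:
    - label: m
      exponent: 2
      calcium_dependent: false
    - label: h
      exponent: 1
      calcium_dependent: false
  Ca_IT2:
    reversal_mV: 140.0
    temperature_factor: 1.947073
    gates:
    - label: m
      exponent: 2
      calcium_dependent: false
    - label: h
      exponent: 1
      calcium_dependent: false
  HCN1:
    reversal_mV: -45.0
    temperature_factor: 1.0
    gates:
    - label: m
      exponent: 1
      calcium_dependent: false
  HCN2:
    reversal_mV: -45.0
    temperature_factor: 1.0
    gates:
    - label: m
      exponent: 1
      calcium_dependent: false
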