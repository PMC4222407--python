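# Channel conductance densities (pS/µm²) per region.
#
# Profiles: uniform; linear (start at region origin -> end_or_factor at the
# region's maximal path distance); exponential (start * exp(±d/λ), growth
# capped at cap_factor * start); linear_exchange (a proximal/distal pair
# sharing a total density, exchanged linearly over `span` µm).
# `extent`/`onset` restrict a rule to a distance window.
#
# Pseudo-channels: HCN is split 2/3 HCN1 : 1/3 HCN2 at assembly; K_A pairs
# are split into K_AP / K_AD by the exchange fraction.
rules:
  # --- soma
  - {channel: Na,     region: soma, profile: uniform, start_density: 420}
  - {channel: Na_P,   region: soma, profile: uniform, start_density: 10}
  - {channel: K_V,    region: soma, profile: uniform, start_density: 20}
  - {channel: K_M,    region: soma, profile: uniform, start_density: 10}
  - {channel: K_BK,   region: soma, profile: uniform, start_density: 0.6}
  - {channel: K_AP,   region: soma, profile: uniform, start_density: 150}
  - {channel: Ca_HVA, region: soma, profile: uniform, start_density: 2}
  - {channel: HCN,    region: soma, profile: uniform, start_density: 0.95}
  # --- axon
  - {channel: Na_x,   region: axon, profile: uniform, start_density: 3500}
  - {channel: K_V,    region: axon, profile: uniform, start_density: 40}
  - {channel: K_M,    region: axon, profile: uniform, start_density: 50}
  # --- apical dendrite
  - {channel: Na,     region: apical, profile: linear, start_density: 350,
     end_or_factor: 320}
  - {channel: K_A,    region: apical, profile: linear_exchange, variant: proximal,
     start_density: 300, end_or_factor: 300, span: 300}
  - {channel: K_A,    region: apical, profile: linear_exchange, variant: distal,
     start_density: 300, end_or_factor: 300, span: 300}
  - {channel: K_V,    region: apical, profile: exponential, start_density: 20,
     length_constant: 80}
  - {channel: K_M,    region: apical, profile: uniform, start_density: 5,
     extent: 100}
  - {channel: K_BK,   region: apical, profile: uniform, start_density: 0.6}
  - {channel: Ca_HVA, region: apical, profile: uniform, start_density: 2}
  - {channel: Ca_IT2, region: apical, profile: uniform, start_density: 0.5,
     onset: 300}
  - {channel: HCN,    region: apical, profile: exponential, grow: true,
     start_density: 0.95, length_constant: 323, cap_factor: 40}
  # --- basal dendrites
  - {channel: Na,     region: basal, profile: linear, start_density: 150,
     end_or_factor: 75}
  - {channel: K_A,    region: basal, profile: linear_exchange, variant: proximal,
     start_density: 150, end_or_factor: 255, span: 300}
  - {channel: K_A,    region: basal, profile: linear_exchange, variant: distal,
     start_density: 150, end_or_factor: 255, span: 300}
  - {channel: K_V,    region: basal, profile: exponential, start_density: 20,
     length_constant: 80}
  - {channel: K_M,    region: basal, profile: uniform, start_density: 5,
     extent: 20}
  - {channel: K_BK,   region: basal, profile: uniform, start_density: 0.6}
  - {channel: Ca_HVA, region: basal, profile: uniform, start_density: 2}
  - {channel: Ca_IT2, region: basal, profile: uniform, start_density: 0.5,
     onset: 300}
  - {channel: HCN,    region: basal, profile: exponential, grow: true,
     start_density: 0.95, length_constant: 323, cap_factor: 40}
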