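# Stylized layer 5 pyramidal cell geometry (µm).
# Deterministic stand-in for a reconstructed morphology: soma, axon initial
# segment + axon, tapering apical trunk carrying a two-branch tuft, and
# three basal dendrites.  Sections are discretized into <= 20 µm segments
# at build time.
sections:
  - {name: soma,   region: soma,   length: 25, diameter: 25}
  # axon = tapering hillock + initial segment; the high sodium density
  # lives only here, as in axon-initial-segment models
  - {name: hillock, region: axon,  parent: soma,    length: 15,
     diameter_start: 3.0, diameter_end: 1.5}
  - {name: ais,     region: axon,  parent: hillock, length: 30, diameter: 1.5}
  - {name: trunk,  region: apical, parent: soma,  length: 620,
     diameter_start: 4.0, diameter_end: 2.6}
  - {name: tuft1,  region: apical, parent: trunk, length: 300, diameter: 1.8}
  - {name: tuft2,  region: apical, parent: trunk, length: 300, diameter: 1.8}
  - {name: basal1, region: basal,  parent: soma,  length: 200,
     diameter_start: 2.6, diameter_end: 1.3}
  - {name: basal2, region: basal,  parent: soma,  length: 200,
     diameter_start: 2.6, diameter_end: 1.3}
  - {name: basal3, region: basal,  parent: soma,  length: 200,
     diameter_start: 2.6, diameter_end: 1.3}
  - {name: basal4, region: basal,  parent: soma,  length: 200,
     diameter_start: 2.6, diameter_end: 1.3}
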