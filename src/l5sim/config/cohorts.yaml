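# Group summaries (mean, SEM) of the paired ex vivo comparisons, used as
# generator presets for synthetic cohorts.  Features: input resistance
# (MΩ), rheobase (pA), F-I slope (Hz/nA), post-train AHP amplitude (mV).
columns:
  4bPMA:
    n: 17
    input_resistance: {control: [74.8, 9.8],  treatment: [105.1, 13.6]}
    rheobase:         {control: [124.1, 16],  treatment: [103.5, 14.1]}
    fi_slope:         {control: [76, 4.9],    treatment: [96, 7.5]}
    ahp_amplitude:    {control: [5.8, 0.3],   treatment: [2.7, 0.3]}
  Bryostatin1:
    n: 7
    input_resistance: {control: [69.13, 15.3], treatment: [87.3, 25.5]}
    rheobase:         {control: [120.8, 20],   treatment: [105.6, 17]}
    fi_slope:         {control: [81, 10],      treatment: [103, 11]}
    ahp_amplitude:    {control: [6.4, 0.64],   treatment: [3.6, 0.42]}
  IFN-beta:
    n: 8
    input_resistance: {control: [76.5, 9.7],  treatment: [89.1, 11.1]}
    rheobase:         {control: [185.2, 28],  treatment: [146.9, 20]}
    fi_slope:         {control: [47.7, 3.9],  treatment: [57.9, 5.3]}
    ahp_amplitude:    {control: [5.0, 0.25],  treatment: [3.4, 0.5]}
  GF109203X+IFN-beta:
    n: 9
    input_resistance: {control: [68.1, 11.2], treatment: [73.3, 10]}
    rheobase:         {control: [148.3, 29],  treatment: [140.6, 24]}
    fi_slope:         {control: [91.1, 9.9],  treatment: [87.8, 6.8]}
    ahp_amplitude:    {control: [3.7, 0.44],  treatment: [3.1, 0.4]}
  calphostinC+IFN-beta:
    n: 12
    input_resistance: {control: [67.7, 10.3], treatment: [74.2, 11.9]}
    rheobase:         {control: [170, 19],    treatment: [200, 17]}
    fi_slope:         {control: [100, 11.8],  treatment: [104, 9.6]}
    ahp_amplitude:    {control: [3.9, 0.5],   treatment: [2.6, 0.4]}
age_range_postnatal_days: [11, 27]
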