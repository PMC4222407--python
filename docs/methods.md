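# Methods

## Model structure

The cell is a tree of cylindrical compartments. The shipped stylized
layer 5 morphology (`config/reference_morphology.yaml`) has a 25×25 µm
soma, a tapering axon hillock plus a 30-µm initial segment, a 620-µm
tapering apical trunk carrying two 300-µm tuft branches, and four
200-µm tapering basal dendrites, discretized into ≤20 µm electrical
segments (105 compartments). Any SWC reconstruction can be used instead
(`morphology.load_swc`); all type-1 samples are merged into a single
equivalent-area soma and path distances accumulate along the 3-D sample
points. The geometry was chosen once so that the passive somatic input
resistance (~79 MΩ) falls in the range typical of juvenile layer 5
neurons; it was fixed before any modulation experiment.

Passive membrane: C_m = 1.5 µF/cm² and R_a = 68 Ω·cm uniformly (the
source prints the resistivity as "68.0 Ω"; Ω·cm is the standard unit and
is assumed — the value is config-exposed). R_m follows a logistic
profile of dendritic path distance from 36.0 kΩ·cm² at the soma to
5.4 kΩ·cm² at the most distal tip, with its midpoint at half the maximal
dendritic path distance and a slope spanning ≥99% of the range — only
"sigmoidal" is prescribed, so the logistic form, midpoint and span are
package choices. Soma and axon take the somatic value. Spines are
incorporated by doubling C_m and all active conductance densities and
halving R_m from 20 µm (basal) / 100 µm (apical) outward, boundary
inclusive; the correction is idempotent and conserves membrane area.

## Channels and kinetics

Twelve Hodgkin-Huxley-style channels are distributed per the published
density table (`config/densities.yaml`): transient Na (somatodendritic)
and the axon-initial-segment variant Na_x (activation 12 mV
hyperpolarized, inactivation unshifted), persistent Na_P,
delayed-rectifier K_V, M-type K_M, proximal/distal A-type K_AP/K_AD
(exchanged linearly over the first 300 µm), BK, high-threshold Ca_HVA,
low-threshold Ca_IT2 (distal, >300 µm), and HCN1/HCN2 (2/3 : 1/3 of the
exponential HCN gradient, λ = 323 µm, capped at 40× the somatic 0.95
pS/µm²). Reversal potentials are fixed (E_Na +60, E_K −90, E_h −45,
E_Ca +140 mV); rates are Q10 = 2.3-scaled to the nominal 32 °C.

The cited kinetic sources are not reproduced in the underlying study, so
the parameterizations are the package's own, built from the standard
forms for each family (trap-function Na/K_V/Ca_HVA rates, Boltzmann
A-type/persistent-Na/HCN/M gates) and then *calibrated as a set* so that
the control and modulated models reproduce the published excitability
pair (see Calibration). The parameters that matter most, with defaults:

- **Na**: activation trap threshold −30 mV; inactivation V½ −62 mV with
  slope 4 mV and 4×-slowed recovery. The steep inactivation keeps the
  subthreshold window current small despite 150-420 pS/µm² of
  somatodendritic Na; the slowed recovery makes Na inactivation a *slow*
  variable near threshold, which destabilizes the accommodated
  subthreshold equilibrium and permits repetitive firing.
- **Na_P** (10 pS/µm², somatic): V½ −48.5 mV, k = 5 mV, τ = 1 ms. Its
  position just below spike threshold makes the rheobase strongly
  sensitive to the −2 mV PKC shift — the dominant single-channel lever.
- **K_V**: trap threshold −20 mV, rates ×1.5. Activating well below the
  spike peak, it acts as a *fast, memory-free* barrier in the
  subthreshold corridor: it sets the rheobase without creating the
  adapted silent states that slow conductances produce.
- **K_M**: Boltzmann V½ −45 mV, k = 12 mV; τ(V) = 80 ms plus a bell
  (peak ≈ 380 ms near −55 mV). The slow component yields slow-AHP
  pacing and spike-frequency accommodation; its shallow slope spreads
  the steady "brake" over the whole subthreshold range.
- **BK** (package's own model): open fraction
  `m∞(V, Ca) = 1/(1+exp(-(V - V½(Ca))/28))` with
  `V½(Ca) = 20 mV − 55 mV·log10(Ca/1 µM)`, τ = 1 ms — monotone in both
  V and Ca and bounded in [0,1]. The moderate slopes matter: a steeper
  surface self-regulates (a density change is absorbed by a small shift
  of steady-state calcium), which would erase the BK modulation's effect
  on firing.
- **Calcium pool**: one sub-membrane shell per compartment, depth
  0.45 µm, first-order decay τ = 130 ms, driven by |I_Ca| from Ca_HVA
  and Ca_IT2. The pool's kick-and-decay dynamics set the medium AHP and
  hence the F-I gain; the decay constant paces near-rheobase firing.
- **HCN1/HCN2**: V½ −90 / −102 mV (k = 9), τ ≈ 30-80 / 200-480 ms —
  HCN1 less hyperpolarized and faster, so the HCN1-specific modulation
  touches the physiologically active subunit.
- **A-type**: n⁴ activation (per-gate V½ −25/−35 mV for the
  proximal/distal variants, k = 12) with a fast inactivation gate; the
  fourth power removes the resting window current that a first-order
  gate of equal midpoint would produce, confining A-type action to spike
  repolarization.

## Numerics

Staggered time stepping: every gate advances one step by exponential
(Rush-Larsen) integration at the present voltages, then the voltage step
is fully implicit (backward Euler) using the updated conductances; the
tree-structured linear system is solved by Hines elimination (O(N)).
Voltage clamp is an ideal somatic clamp implemented as a 1 S penalty
conductance. Default dt = 0.025 ms, recordings at 0.05 ms; every
protocol starts from a cached 2-s settle at 0 pA, and step families are
re-initialized between amplitudes (standing in for the long experimental
inter-step interval). Outputs are bit-stable across runs. Non-finite
states abort with the offending compartment and time. The M-current tail
protocol measures the tail 20 ms after the deactivating step — past the
axial/capacitive redistribution of the unclamped dendrites — minus the
steady-state current; with confounding channels masked the tail scales
with g_KM to within 2%.

Known numerical limitation: at amplitudes sitting exactly on the
tonic-firing onset edge, the 1-s spike count can change by one when dt
is halved (observed at a single amplitude of the reduced grid). The
count there is genuinely bifurcation-sensitive; everywhere else counts
are dt-invariant.

## Calibration and the modulation experiments

Absolute kinetics of the cited channel families are not the scientific
content here — the calibrated control/modulated *ratios* are. The
somatic/axonal Na, Na_x and K_V densities may be rescaled within ±30% of
the table values; the recorded calibration (`config/biophys.yaml`) is
K_V ×1.05 with Na/Na_x untouched. With it the control model fits
(rheobase 283 pA, F-I slope 70.0 Hz/nA) and the PKC-modulated model
(157 pA, 100.0 Hz/nA): slope ratio 1.43, rheobase ratio 0.55, AP
voltage threshold unchanged (<0.2 mV; <0.6 mV under a −4 mV Na_P
shift). Every proper subset of the four modulations reaches less than
80% of the full set's slope increase or rheobase decrease (the
"necessity" criterion; the 80% cut-off is a package choice, the source
states failure only qualitatively). Single-modulation contributions are
ranked by fractional rheobase reduction — robust under the amplitude
grid's count quantization, unlike fitted-slope ratios of single
modulations — giving HCN1 < K_M < K_BK < Na_P.

One caveat the tests record honestly: the calibrated control cell fires
a single action potential ~16 ms after step onset at 200-350 pA (an
overshoot transient carried by slow HCN deactivation and M-current lag)
before accommodating to silence; fully silent behaviour at 250 pA, as
the in-silico reference reports, is not reproduced. Sustained firing
still begins only near 400 pA, and the modulated model fires 10 spikes
at 250 pA, so the qualitative contrast stands.

## Feature extraction

Spikes are upward crossings of −10 mV with a 2-ms refractory period
(model and fixture APs overshoot 0 mV). The F-I fit uses the *first
linear portion*: starting at the first amplitude with a sustained train
(≥3 spikes — an isolated 1-2-spike step-onset transient is not a rate),
skipping leading points whose successive rate increments disagree by
more than 2.5× (onset curvature), then extending 2-5 points while
R² ≥ 0.98 and the incremental slope stays above half the initial
pairwise slope. The rheobase is the fit's abscissa intercept. The
published procedure restricts the fit to the linear proportion by eye;
these rules are the package's operationalization of that judgement.
Input resistance is the least-squares I-V slope of the steady-state
voltages (last 200 ms) of the ±50/0 pA steps. AHP amplitude is the
settled post-stimulus potential (last 100 ms) minus the deepest
hyperpolarization within 500 ms of stimulus offset, after 2-ms smoothing
(which removes the noise-minimum bias), floored at 0. The AP voltage
threshold is the membrane potential at the first local maximum of
d³V/dt³ (quartic Savitzky-Golay over ~1 ms) within 10 ms before the
first spike peak; sampling coarser than 0.1 ms is rejected.

## Synthetic data

No raw per-cell recordings exist for the paired design — only group
means ± SEM. The cohort generator draws per-cell baselines log-normally
around the control means (features are positive and right-skewed),
applies a multiplicative treatment effect with an optional linear age
dependence (ages uniform on P11-P27; a named scenario reproduces a
negative input-resistance-effect-vs-age trend), and adds Gaussian
measurement noise to both arms; non-positive draws are redrawn, and
specs whose underlying non-positive rate exceeds 1% are rejected.
Presets derive dispersion from the tabulated SEMs with an 80/20
biological/measurement variance split (a free parameter — the tabulated
SEMs conflate the two). The trace-fixture generator inverts the feature
extractor: RC subthreshold responses, stereotyped spikes at the rate
implied by the target F-I line (counts are integers, so recovered
rheobase/slope are quantized by the 50-pA grid), and an alpha-shaped AHP
of exactly the target depth. What passing these tests shows is that the
extraction and statistics stages are correct and well-calibrated; they
do not certify behaviour on real recordings, which contain artifacts
(electrode drift, series-resistance error, bursting) the generator
deliberately omits.

## Statistics

Paired comparisons use Shapiro-Wilk (α = 0.05) on the paired
differences; the Wilcoxon signed-rank test (exact null for n ≤ 25) is
used for n < 8 or non-normal differences, the paired t-test otherwise.
Zero-variance differences yield a degenerate result flagged with p = 1.
Percent changes are reported unrounded and rounded half-to-even; no
multiple-testing correction is applied. Note that the published "about
N%" statements differ from printed-group-mean arithmetic by up to one
percentage point for several comparisons; the package always reports
the computed value.

## Problem sizes

The default analyses use the 13-amplitude 50-pA grid for the control and
modulated F-I characterizations and a 7-amplitude 100-pA grid for the
16-model subset analysis and multi-model checks; synthetic recovery
suites use n = 200 cells and 50 noise seeds. These sizes keep the full
test suite and the acceptance computation within a few minutes on one
CPU while leaving all reported quantities well-resolved.
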