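# Methods

## Model

Neurons are leaky integrate-and-fire units with spike-frequency adaptation:

    dv_i/dt = f_i(t) + s_i(t) − v_i/τ_m − γ a_i(t),   v_i < θ
    v_i → v_i − θ                                      when v_i reaches θ
    ds_i/dt = −s_i/τ_s + Σ_j w_ij δ(t − t_spike^j)
    da_i/dt = −a_i/τ_a + δ(t − t_spike^i)

Units: voltages in mV, times in ms, drive f and synaptic input s in mV/ms;
rates are reported in Hz. Defaults: θ = 20 mV, τ_m = 20 ms, τ_s = 2 ms,
h = 0.1 ms; (τ_a, γ) = (350 ms, 0.44) for the discrete case example and
(650 ms, 0.013) for the continuum case example. The adaptation increment per
spike is exactly 1; γ carries all scaling.

**Adaptation acts on excitatory neurons only** (`NeuronParams.adapt_e_only`,
default on). This is a deliberate modelling decision at a point the equations
leave open. Fast-spiking inhibitory interneurons show little spike-frequency
adaptation physiologically, and the choice is dynamically forced here: if
inhibitory neurons adapt with the same (τ_a, γ), the adapting interneurons
blunt the disinhibition loop that sustains winner-take-all competition, and
at the discrete case-example parameters the network either locks into a
permanent winner or flickers without seconds-scale dominance epochs. With
excitatory-only adaptation the printed parameters produce rivalry directly.

## Integration scheme

The voltage is advanced with a Heun (modified Euler) step; the linear traces
s and a decay exactly (`exp(−h/τ)`) within a step. A neuron whose voltage
ends the step at or above θ fires: the spike time is assigned by linear
interpolation between the step-endpoint voltages, and the reset v → v − θ is
applied at the end of the step. Synaptic kicks from spikes in a step are
applied to the postsynaptic s at the end of that step, weighted by
`exp(−(t_end − t_spike)/τ_s)` to honor the interpolated spike time
(`weight_interp=False` gives the plain un-weighted kick; a first-order Euler
voltage update is available as `scheme="euler"`). One reset per step: a
neuron driven past 2θ by a synchronous barrage (this happens transiently at
dominance switches) stays above threshold and fires again the next step, so
per-neuron ISIs are bounded below by h. A non-finite state aborts the run
naming the first offending neuron.

Sensitivity: on the discrete case example, halving h changes population rates
and mean CV_ISI by well under 5% (asserted in the test suite); near the
rivalry operating point the individual dominance-epoch boundaries are
chaotic, so h affects individual trajectories while leaving the statistics
consistent.

Initial conditions: v uniform on [0, θ) from the run seed, s = a = 0. The
first 2 s are discarded as burn-in for all statistics (configurable).
Identical (connectivity, drive realization, seed) reproduce rasters bit for
bit.

## Architectures

All builders are seeded and deterministic.

* **Unstructured** (n = 4000, k = 600): even E/I split; every neuron receives
  synapses from each afferent class with weight ±A_xy/√k, A_ee = 12.5,
  A_ie = 20, A_ei = 50, A_ii = 50 (A_xy is the amplitude from class y onto
  class x).
* **Discrete mutual inhibition** (n = 4000, k = 200 per pool): two
  unstructured pools of 1000 E + 1000 I; additionally every I neuron receives
  k long-range excitatory synapses from the opposite pool. Case example:
  A_ee = 10.5, A_ei = 20, A_ie = 30, A_ie_long = 30, A_ii = 45, over √k.
* **Continuum** (n = 4000, 80% E): neurons evenly on a ring, each ordered
  pair connected with probability p = 0.34, weight
  A·exp(κ·cos Δ)/(p·N_post·2π·I₀(κ)) with the afferent sign by presynaptic
  class. N_post is the postsynaptic class size. Case-example values:
  A_ee = 84, A_ei = 314, A_ie = 1319, A_ii = 689; κ_ee = 0.26, κ_ei = 0.93,
  κ_ie = 0.97, κ_ii = 0.5 (the κ_ii value is exposed as a config key: the
  published parameter list repeats κ_ee where κ_ii is expected, so this
  assignment is a reconstruction).

**In-degree distribution.** "k randomly chosen connections" is implemented as
independent Bernoulli wiring with connection probability k/N_pre (mean
in-degree k, binomial variance). The zero-variance alternative (exactly k
partners per neuron) is available as `in_degree="fixed"` but is not the
default, because the quenched heterogeneity of the binomial graph is
dynamically essential: with identical in-degrees every neuron in a population
sees statistically identical input, the population synchronizes into
burst-silence cycles under shared drive, the suppressed pool of the discrete
network is uniformly below threshold (hence totally silent rather than
sparsely active), and the unstructured network cannot sustain asynchronous
irregular activity at low rates at all. With binomial wiring the in-degree
spread (~7% at k = 200) desynchronizes the populations and produces the
sparse, irregular suppressed-pool firing the rivalry phenomenology requires.

## Drive

Drive is organized in groups of neurons sharing one time course.

* Constant drive: the structured (discrete, continuum) case examples drive
  excitatory neurons only; the discrete example drives all E neurons at
  5 mV/ms, the continuum example two arcs of E neurons (half-width 45°,
  a convention — the stimulated-arc width is not pinned by the published
  description) centered at ring positions 0 and π.
* Heterogeneous OU drive (unstructured): the two E half-populations receive
  independent Ornstein–Uhlenbeck processes (mean 0.2), all I neurons a third
  (mean 0.1), stationary SD 1, correlation time 500 ms. "SD" is the
  *stationary* standard deviation; the exact discrete-time update
  x ← μ + (x−μ)e^(−h/τ) + σ√(1−e^(−2h/τ))·ξ preserves it at any h. Negative
  excursions are kept (a clip-at-zero switch exists for sensitivity
  analyses).
* Homogeneous drive (unstructured): the published description fixes only
  "slightly higher" E than I drive without values. The preset uses
  E = 2.0, I = 1.0 mV/ms: a 2:1 ratio at a suprathreshold mean that sustains
  the asynchronous irregular balanced state at a few Hz. (Re-using the OU
  means 0.2/0.1 leaves a finite network silent — the mean drive is far
  subthreshold and there is no external fluctuation source in this
  condition.) Homogeneous-case claims are qualitative only.
* Levelt scans: symmetric (both pools) or pool-A-only piecewise-constant
  grids.

## Percept readout and dominance statistics

Pooled excitatory counts u_A, u_B in non-overlapping 50 ms windows give
P = (u_A−u_B)/(u_A+u_B); windows are labeled A (P > 1/3), B (P < −1/3) or
neither. Boundary values and empty windows are "neither".

**Report-threshold filtering.** The reported percept changes at the start of
any *run* of windows with a different label — A, B, or neither — lasting at
least the report threshold (default 300 ms). Shorter runs are sub-threshold
events and are absorbed into the ongoing epoch (the duration clock keeps
running); a qualifying neither-run terminates the epoch without opening a
new one. A dominance duration is the interval between reported state
changes. With threshold 0 this reduces to the raw labeled runs. First and
last epochs are censored and excluded from duration statistics; statistics
require at least two completed epochs, otherwise they are flagged undefined.
The absorb policy is the default; a drop policy (epochs end at their last
qualifying run) exists for comparison.

Duration statistics: mean, SD (ddof = 1), CV_D, adjusted Fisher–Pearson
(bias-corrected) skewness — documented because the skewness/CV_D ratio is
sensitive to the estimator — and gamma shape/scale by maximum likelihood
with location fixed at zero. The σ–μ regression across drive strengths is
ordinary least squares through the origin, so the slope is interpretable as
an overall CV_D; a with-intercept variant is available.

State-conditioned spiking statistics use a per-window mask: pool A is
dominant in reported-A epochs (and suppressed in reported-B epochs), but
windows whose raw label disagrees with the reported percept are excluded
from both states. CV_ISI pools ISIs within contiguous same-state intervals
(never across a state change; at least 3 ISIs per neuron). Fano factors and
pairwise spike-count correlations use 100 ms windows tiled within state
intervals (at least 20 windows; zero-mean neurons and zero-variance pairs
excluded; 1000 seeded within-pool E–E pairs by default).

## Balanced-state mean-field theory

Population rates in the balanced state solve W r + f = 0. For the discrete
architecture the effective weight from population y to x is
w_xy = √k·A_xy·τ_s with rates in spikes/ms (each neuron receives on average
k synapses of amplitude A/√k, and one spike injects a synaptic-current
integral of w·τ_s). The two-pool matrix couples the pools only through the
long-range E→I entries. The solver reports all pathologies as states rather
than exceptions: rank-deficient W with f outside its column space (no
balanced state — the symmetrically coupled network under asymmetric drive),
and negative rate components (infeasible; the network pins that population
at zero instead). |det W|/‖W‖⁴ < 1e−12 declares singularity. Sweeps over the
mutual-inhibition weight locate the det(W) = 0 point by bisection; the
singular direction is the antisymmetric pool mode, so solutions under
asymmetric drive diverge approaching it while the symmetric-drive solution
passes through smoothly. Theory–simulation comparisons fit one global scale
factor on the symmetric branch (least squares over all populations), then
freeze it; all claims are about curve shape and regime boundaries, never
absolute rates.

## Synthetic ground-truth rasters

`rivalsim.synthetic` generates Poisson, periodic, gamma-renewal and
alternating-two-pool rasters in the same `SpikeRaster` container the
simulator emits, so every measure is validated against analytic ground truth
(CV_ISI = 1 and Fano = 1 for Poisson, CV_ISI = 0 for periodic, CV_D = 1/√shape
for gamma epochs, exact epoch boundaries for the two-pool generator). These
fixtures emulate firing-rate structure only — they contain no synaptic
interactions, adaptation or balanced-state correlations — so passing them
validates the *measurement pipeline*, not the network model.

## Problem sizes

The bundled tests and the reproduction script use desk-scale runs chosen as
the package's own defaults: ~2 minutes of biological time for the
case-example spiking statistics (≈100 dominance epochs), 100 s per drive
point on 10-point scans, and ~37 minutes of biological time for the
OU-driven unstructured run (≈130 reported epochs at the 300 ms threshold).
Sample sizes are recorded alongside every reported quantity.

## Known limitations

* **Dominance-duration variability is lower than empirical.** The discrete
  case example alternates with CV_D ≈ 0.2 at the printed parameters (the
  empirical band is 0.4–0.8): switching is more adaptation-clocked, and the
  balanced-state fluctuations contribute less variance, than in the source
  system. Consequently the σ–μ regression slope across drives (~0.2) also
  falls below the reported ~0.65, the skewness/CV_D ratio is noisier and
  higher than the reported ~3, the heavy tail of un-thresholded dominance
  events in the OU-driven unstructured run is lighter than reported
  (CV_D ≈ 1.1–1.3 vs ~1.9 at threshold 0), and the suppressed-state
  spike-count correlations sit slightly above the reported 0.06
  (≈ 0.10 — the sparse suppressed-pool spikes are strongly driven by the
  common dominant-pool fluctuations). The state-conditioned spiking statistics
  (CV_ISI, r_sc, Fano), rates, Levelt propositions, the opposite drive-trends
  of CV_D and CV_ISI, and the threshold-sensitivity contrast with the
  unstructured network are all reproduced. The discrepancy most likely traces
  to residual ambiguity in the wiring and integration conventions, to which
  the escape dynamics near the winner-take-all boundary are sensitive.
* **The continuum case example does not rival under the published
  parameters.** With footprints maximal at the presynaptic neuron
  (exp(κ·cos Δ)), cross-arc inhibition is strictly weaker than
  self-inhibition for every pathway, for every κ ordering and normalization
  we tested, and the two driven arcs settle into stable coactivation
  (normalization) rather than winner-take-all. A two-pool reduction of the
  ring shows WTA would need κ_ee, κ_ii ≫ κ_ei, κ_ie — the opposite of the
  printed ordering — and the printed list is known to be corrupt (κ_ee
  appears twice). The architecture, drive and measurement code fully support
  the continuum model; the continuum-specific headline numbers are therefore
  not reproduced, and the corresponding checks in the acceptance test suite
  fail with an explanatory message.
* The mean dominance duration at the case-example drive (~1 s) is at the
  short end of the seconds scale; absolute durations are sensitive to the
  operating point and were not calibrated.
* No synaptic delays, no conductance-based synapses, no synaptic depression
  (adaptation is the only fatigue mechanism), no plasticity, and the
  mean-field layer covers the discrete/unstructured architectures only.
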