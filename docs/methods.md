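# Methods

## The model

`semibalance` implements the theory of *semi-balanced* excitatory–inhibitory
networks and the simulators needed to test it. A recurrent network of `n`
neural populations driven by external populations is summarized by effective
matrices

```
W[a, b]  = j_ab · p_ab · N_b / N^s        (recurrent, mV/Hz)
Wx[a, x] = j_ax · p_ax · N_x / N^s        (feedforward)
X        = Wx · r_x                        (external drive, mV)
```

where `j_ab` is the mean synaptic strength, `p_ab` the connection
probability, `N_b` the presynaptic population size, and `s` the
weight-scaling exponent (default 1/2, the classical strong-coupling scaling
`J ~ 1/sqrt(K)`; configurable). The coupling scale
`JK = mean(|j_ab·p_ab·N_b|/N^s)` over nonzero blocks is reported as a
diagnostic; it cancels in the fixed-point equations, so mean-field rates do
not depend on it.

Two regimes are solved:

* **Balanced**: excitation and inhibition cancel for every population, so
  rates satisfy the linear equation `r = −W⁻¹X`. Valid only when all entries
  are positive — and for every Dale-compliant `W` there exist strictly
  positive stimuli for which they are not (`breaking_stimulus` constructs
  one: choose `v` negative on excitatory, positive on inhibitory indices and
  take `X = −Wv`).
* **Semi-balanced**: only excess *excitation* is forbidden. Populations with
  excess inhibition are silenced and the active populations form a balanced
  sub-network. Rates solve the threshold-linear fixed-point equation
  `r = [Wr + X + r]⁺`, equivalent to three per-population conditions:
  `[Wr+X]_a ≤ 0`; `[Wr+X]_a < 0 ⇒ r_a = 0`; `r_a ≥ 0`
  (`verify_semibalance` checks them; the equation is invariant to replacing
  `r` with `c·r` inside the rectification for any `c > 0`, which
  `scale_invariance_check` exercises).

`semibalanced_rates` enumerates all `2^n` candidate supports exactly for
`n ≤ 20` (each support yields a linear subsystem), deduplicates boundary
cases at a tolerance of 1e-8 mV, and reports uniqueness or multiplicity; the
full-support (balanced-consistent) solution is searched first and becomes
the primary one. Above `n = 20` a damped fixed-point iteration
(damping 0.1, relative tolerance 1e-10, at most 1e5 iterations) is used and
its answer is verified before being accepted.

## Rate dynamics

`rate_dynamics` integrates `τ·dr/dt = −r + f(s·(Wr + X))` by forward Euler
(τ default 10 ms, dt default 0.1·τ, automatically shrunk when the local
gain makes the system stiff; divergence above 1e5 Hz stops integration).
Three f-I curves are supported: rectified linear (gain 1 Hz/mV),
rectified square `k·[u]⁺²` with `k = 10 Hz/mV²` (the stabilized
supralinear network, SSN), and a saturating sigmoid with ceiling `M`.
Fixed points of the rectified-linear model are found exactly by support
enumeration with dynamical-stability filtering; nonlinear models use
integration plus a Newton polish, and the strong-coupling limit study uses
an active-set boundary-layer solve (`(Wr+X)_S = f⁻¹(r_S)/s` on the support)
with continuation in the coupling scale, which remains well conditioned
where explicit integration becomes hopeless. As the coupling scale grows,
fixed points approach the semi-balanced solution, with populations silenced
in the limit going to zero rate.

**ISN classification.** At an SSN fixed point the Jacobian is
`(−I + diag(2ks[u]⁺)·sW)/τ`; the network is inhibitory-stabilized (ISN)
when the full spectrum is stable but the excitatory submatrix (inhibitory
row and column removed) has an eigenvalue with real part above 1e-8.
A finding worth recording: with the bundled three-population weights at
their full coupling scale, every stable fixed point along the stimulus
sweep is ISN — the supralinear gain `2k·u·w_ee` stays above one whenever an
excitatory population fires above ~0.01 Hz, and the strong inhibitory
self-coupling prevents fully silenced excitation. The stimulus-driven
ISN ↔ non-ISN transition that defines SSN phenomenology appears at weaker
coupling (`JK ≈ 0.1–0.15 mV/Hz`): non-ISN around the competitive switch
where rates are low, ISN where drive and rates are high. The sweep test and
the `ssn-sweep` CLI default therefore run at `JK = 0.15 mV/Hz`.

## Spiking simulator

`spiking` simulates adaptive exponential integrate-and-fire neurons
(τ_m = 15 ms, E_L = −72 mV, Δ_T = 1 mV, V_T = −55 mV, threshold 0 mV,
reset −72 mV, floor −85 mV, adaptation increment 0.75 mV with τ_w = 200 ms)
with exponential synapses (τ = 8/4/10 ms for e/i/x sources) in current or
conductance form; conductance weights are rescaled by `(E_e − V_0)` and
`(E_i − V_0)` with `E_e = 0`, `E_i = −75`, `V_0 = −55 mV`, so the same
effective matrices predict rates for both synapse models. Connectivity is
Bernoulli per ordered pair with weight `j_ab/N^s`; external spikes are
independent Poisson processes realized per external neuron by per-step
thinning (`rate·dt ≤ 0.1` asserted). Euler step dt = 0.05 ms by default.
Update order within a step: synaptic/trace decay → membrane update →
threshold test and reset → spike propagation → plasticity; under a fixed
seed, spike trains are bit-exact reproducible. The rheobase
`(V_T − E_L) − Δ_T = 16 mV` normalizes reported currents.

The weight-scaling exponent was calibrated against single-synapse physics:
with `s = 1/2` the three-population weight table at `N = 3×10⁴` produces
postsynaptic potentials of 0.07–0.54 mV, a physiological range, whereas
`s = 1` gives values two orders of magnitude too small. Two transcription
ambiguities in the source weight tables were resolved the same way: the
inhibitory self-coupling is taken as `j_ii = −3.75 mV/Hz` (the tenfold
weaker variant that appears in one tabulation makes the balanced state
infeasible for every nonnegative stimulus, and −3.75 also reproduces the
quoted coupling scale `JK = 5.9 mV/Hz` exactly), and the one-population
weight table is read in mV·ms (giving feedforward weights identical to the
three-population table). The as-printed variant remains available via
`fixture(..., j_ii=-0.375)` and is the one used for the PSP-range check.

**iSTDP.** The homeostatic inhibitory plasticity rule keeps a spike trace
per neuron (`τ_x = 200 ms`, jump 1 on the owner's spike). On an excitatory
spike, incoming i→e weights change by `−η·x_i(pre)`; on an inhibitory
spike, outgoing weights change by `−η·(x_e(post) − α)` with `α = 2`,
implying a target excitatory rate `α/(2τ_x) = 5 Hz`. Weights are clipped at
zero (crossings counted). The learning rate η is a free parameter of the
rule; the default used throughout (0.06 mV·ms per pairing event, about
1.2% of the initial mean i→e weight at `N = 2000`) was chosen so that a
`N = 2000` network converges to the target rate within ~20–30 s of
simulated time. Larger η converges faster at the cost of weight noise; the
steady-state rate is insensitive to it (observed ≈ 5.3 Hz at 30 s,
within the ±1 Hz acceptance band).

**Two-layer classification.** Layer 1 is the one-population network with
its Poisson drive replaced by its time-constant mean and pixels projected
onto blocks of consecutive excitatory neurons (10 per pixel, 20 mV per unit
pixel value). After iSTDP training the inhibitory weights are frozen and
rate vectors are recorded per image. The one-hot ℓ² readout is solved in
closed form (relative ridge 1e-8 for rank-deficient inputs; argmax
classification with ties to the lowest label). The interlayer rule accrues
pixel-pooled rates into the row of the label, then normalizes columns and
rows to unit norm (order configurable; the normalization makes the learning
rate immaterial), keeping all weights nonnegative. Layer 2 is a competitive
network (one excitatory population per class, mutually uncoupled, shared
inhibition) driven by the layer-1 rates through the expanded interlayer
matrix as mean input, normalized so the peak drive is 20 mV; the predicted
label is the most active excitatory population in each window (ties to the
lowest index, flagged; silent windows abstain). Driving layer 2 with the
mean input image rather than individual layer-1 spikes is a deliberate
simplification: it preserves the quantity the winner-take-all dynamics read
out (window-averaged drive) at a fraction of the cost.

## Analysis

* `balance_metrics`: β = |E + I|/E from window-averaged currents (ratio of
  means, matching population-current plots; per-neuron variant available)
  and c = mean(E)/std(E) per neuron over time bins; undefined entries are
  flagged, never dropped.
* `current_skewness`: bias-corrected sample skewness. In the detailed
  semi-balanced state the per-neuron total-input distribution is
  left-skewed: excess inhibition is allowed, excess excitation is not.
* `pca_residual_variance` / `isomap_residual_variance`: percent variance
  unexplained per dimension. The Isomap residual follows the classical
  definition, `100·(1 − R²)` between geodesic (k-NN shortest-path,
  k default 10) and embedded distances; a disconnected neighbor graph
  falls back to the largest component with a note.
* `svd_imbalance_diagnostic`: singular values of the neuron-level
  connectivity sorted ascending; with `ρ₀` (default 3× the median) the
  fraction of squared stimulus norm in the small-σ left subspace is
  computed. A fraction bounded away from zero (threshold 0.01) means the
  recurrent input cannot cancel the stimulus there — single-neuron balance
  is impossible, which is why random high-dimensional stimuli force
  detailed imbalance while mean-field (population) balance can stay tight.

## Synthetic data

The generator module provides the study conditions: the fully resolved
network presets; the distributed two-dimensional stimulus
`Z = σ₁Z₁ + σ₂Z₂` with standard-normal component vectors fixed per seed
(protocols: fixed σ = 22.5 mV, uniform resampling on [−30, 30] mV every
2 s, and a 17×17 lattice on [−18, 18] mV — 289 points at full scale); and
a digit-like image generator (seven-segment stroke glyphs plus Gaussian
pixel noise, clipped to [0, 1], default 20×20, deterministic per seed)
standing in for handwritten-digit data so everything runs offline. The
stand-in captures class-consistent strokes with controllable overlap but
none of the within-class style variability of real handwriting, so
classification results demonstrate the representation mechanism, not
benchmark performance; published benchmark figures are out of scope by
design. An image side of 10 pixels is used in the pipeline tests to keep
layer 1 at 1000 excitatory neurons.

## Problem sizes used in tests

Desk-scale runs use N = 5000 (spiking vs mean-field, 5 s), N = 2000
(iSTDP homeostasis, 25–30 s; manifold lattice 7×7 at 2.5 s per stimulus),
and 4-class 10×10 digit sets (120 images). At these scales the mean-field
comparison is made at operating points where all populations fire at ≳7 Hz;
near-threshold populations (≲2 Hz) show finite-coupling deviations beyond
20% because the balanced prediction's sensitivity to O(1/JK) corrections
grows as rates approach zero — visible in the competitive preset near
symmetric drive, where the difference mode between the two excitatory
populations is weakly constrained. Full-scale manifold statistics
(sub-2% Isomap residuals at 289 stimuli) are replaced by the ordering
property (Isomap residual < PCA residual at dimension 2), which is the
scale-independent signature of a curved manifold.

## Known limitations

* No synaptic delays, no short-term plasticity, no excitatory plasticity.
* Stability of semi-balanced supports is not analyzed beyond the ISN check;
  multistable competitive regimes report all admissible solutions but not
  their basins.
* The layer-2 network receives mean input, not spike trains, from layer 1.
* Isomap residuals depend on the neighborhood size at small sample counts;
  the choice (k = 10) is recorded in output metadata.
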