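# semibalance

Theory and simulators for **semi-balanced excitatory–inhibitory networks** —
cortical circuit models in which strong excitation must be canceled by
inhibition, but excess inhibition is allowed.

Classical balanced-network theory predicts population rates
`r = −W⁻¹X` from the effective connectivity `W` and external drive `X`;
it is linear in the stimulus, and it breaks down whenever the predicted
rates go negative — which happens for *every* Dale-compliant connectivity
at some strictly excitatory stimuli. In the semi-balanced state that takes
over, populations receiving excess inhibition are silenced and the rest
form a balanced sub-network; rates solve the threshold-linear fixed-point
equation

```
r = [W r + X + r]⁺ ,
```

equivalently: no population has excess excitation, excess inhibition
silences, and rates are nonnegative. The piecewise-linear map from `X` to
`r` makes the network a recurrent rectified-linear unit: it represents
stimuli nonlinearly and can compute functions (XOR, sub-linear contrast
summation, separable image representations) that no balanced network can.

The package provides:

* `meanfield` — construction of `W`, `Wx` from population specifications
  (`j_ab`, `p_ab`, sizes), the balanced and semi-balanced solvers with
  exhaustive support enumeration, condition verification, scale-invariance
  checks, and the constructive balance-breaking stimulus.
* `rate_dynamics` — forward-Euler rate models (threshold-linear and the
  stabilized supralinear network `τṙ = −r + kJK̄[Wr+X]⁺²`), fixed-point
  solvers, inhibitory-stabilization (ISN) classification, and
  strong-coupling limit studies.
* `spiking` — an adaptive exponential integrate-and-fire network simulator
  (numba) with current- or conductance-based synapses, Poisson external
  drive, per-neuron DC stimuli on schedules, homeostatic inhibitory STDP,
  and full recording of spikes, membrane traces and E/I current
  decompositions.
* `learning` — the iSTDP rule at event level, closed-form one-hot
  least-squares readouts, the supervised Hebbian interlayer rule, and
  winner-take-all evaluation.
* `analysis` — balance metrics (β = |E+I|/E, c = mean/std of E), current
  skewness, PCA and Isomap residual-variance curves, and the SVD
  detailed-imbalance diagnostic.
* `synthetic` — fully resolved network presets, distributed
  two-dimensional stimuli `Z = σ₁Z₁ + σ₂Z₂`, stimulus lattices, and a
  deterministic digit-like image generator for offline classification
  experiments.
* a CLI, `semibalance`, exposing reproducible scenario runs.

## Worked example: contrast-dependent summation

A four-population receptive-field model (`e1, e2, i1, i2`) sums
low-contrast stimuli linearly and high-contrast stimuli sub-linearly:

```
$ semibalance contrast-demo
--- stimulus X1low: X = [0.4  0.3  0.15 0.05] mV
population	rate_Hz	residual_mV	in_support
e1	11.6667	5.55112e-17	1
e2	7.66667	5.55112e-17	1
i1	7.5	2.77556e-17	1
i2	3.5	1.38778e-17	1
...
--- stimulus X1high: X = [0.8  0.3  0.25 0.1 ] mV
population	rate_Hz	residual_mV	in_support
e1	32.5	-1.11022e-16	1
e2	0	-0.1	0
i1	18.75	0	1
i2	0	-0.025	0
```

At low contrast every population is active (full support, a balanced
network: residuals vanish) and responses to the two receptive fields add
exactly. The high-contrast stimulus silences `e2` and `i2` — their
residual input is negative (excess inhibition, −0.1 and −0.025 mV) — and
the joint response `(29.67, 29.67, 17.17, 17.17)` Hz falls below the sum
of the individual responses: sub-linear summation, a population-level
nonlinearity impossible in the balanced regime.

The same library calls from Python:

```python
from semibalance import fixture, semibalanced_rates
fx = fixture("contrast_demo")
sol = semibalanced_rates(fx.net, fx.stimuli["X1high"])
sol.r        # array([32.5 ,  0.  , 18.75,  0.  ])
sol.support  # (0, 2)
```

Other scenarios: `semibalance solve --preset fig1_linear --rx 0,30`
(balanced vs semi-balanced regime report), `semibalance spiking`
(scaled-down spiking run against the mean-field prediction),
`semibalance istdp` (homeostatic convergence to the 5 Hz target),
`semibalance manifold`, `semibalance classify`,
`semibalance diagnose-imbalance`. Every run writes delimited-text outputs
and a `manifest.json` with the resolved configuration and seeds.

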