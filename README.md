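# bindgeom

Tools for studying how neural populations solve the **binding problem** for
value: when two offers are on the screen at once, the brain must represent
not just *which* values are present but *which value belongs to which offer*
(its side, its presentation order).  A perfectly factorized population code —
one shared value axis plus independent axes for side and order — generalizes
beautifully across contexts but cannot distinguish "high-left, low-right"
from "low-left, high-right": the two stimulus sets produce identical mean
responses, and a maximum-likelihood decoder misbinds at chance.  Adding a
*conjunctive* (nonlinearly mixed-selective) component breaks that ambiguity
at the cost of making the value code less shared across contexts.

`bindgeom` implements an analytic theory of this tradeoff for
linear–nonlinear population codes, simulators that validate it, and the full
estimation pipeline needed to apply it to trial-by-neuron firing-rate tables
from a sequential risky-choice task.  It is written for systems /
computational neuroscientists analyzing population recordings.

## The model

Responses of `N` neurons to a discrete stimulus `x` (here: `K = 2` features
— binarized offer value and a bound variable such as side — with `n = 2`
levels each) are

```
r(x) = L x_z + M f_N(x) + noise,     noise ~ N(0, sigma^2 I)
```

where `L` has orthogonal columns of length `dLV` (value) and `dLA` (side or
order), and `M` holds one orthogonal conjunctive column per stimulus, each of
length `m = dN / sqrt(2)` so any two stimuli are `dN` apart in the nonlinear
part.  Writing `Q` for the standard normal CDF, the theory gives in closed
form:

* **overall ML decoding error** (union bound over lattice neighbours):
  `P(err) = N_C Q(-d_C / 2 sigma) + N_{C+1} Q(-d_{C+1} / 2 sigma)` with
  `d_C = sqrt(dL^2 + dN^2)`, `d_{C+1} = sqrt(2 dL^2 + dN^2)`;
* **misbinding error** for a pair of stimuli:
  `P(bind) = N_S Q(-d_S / 2 sigma)` with `d_S = sqrt(2) dN` and `N_S` the
  mean chimera count (`1/4` for the 2x2 task) — independent of `dLV`, `dLA`;
* **cross-condition generalization error** of a prototype decoder:
  `P(gen) = Q(-(1/sigma) * dLV^2 / (2 sqrt(dLV^2 + dN^2 + eps^2)))` —
  independent of `dLA`;
* the **subspace correlation** that links them:
  `rho = dLV^2 / (dLV^2 + dN^2)`.

The estimation pipeline recovers `dLV, dLA, dN` from data by cross-validated
(crossnobis) condition distances decomposed with non-negative least squares,
estimates `sigma` along the value decoding axis and the standard-error
distance `eps` from finite-trial centroids, and feeds them back into the
formulas to predict binding and generalization error rates — which can be
compared against direct SVM decoding on the same data.

## Worked example

```python
from bindgeom import synthetic_data as sd, geometry_decomposition as gd
from bindgeom import subspace_geometry as sg
from bindgeom.theory import CodeParams

params = CodeParams(dLV=1.0, dLA=0.8, dN=0.8, sigma=0.5)
session = sd.generate_discrete_session(120, params, n_trials_per_condition=300, seed=0)

decomp = gd.decompose_session(session.rates, session.labels["condition"],
                              n_boot=100, seed=0)
pred = gd.predicted_error_rates(decomp)
print(f"dLV = {decomp.dLV:.3f}   dLA = {decomp.dLA:.3f}   dN = {decomp.dN:.3f}")
print(f"sigma = {decomp.sigma_hat:.3f}   epsilon = {decomp.epsilon_hat:.3f}")
print(f"subspace correlation rho = {decomp.subspace_correlation:.3f}")
print(f"predicted binding error        = {pred['binding_error']:.4f}")
print(f"predicted generalization error = {pred['generalization_error']:.4f}")

est = sg.estimate_subspace_correlation(session, n_boot=100, seed=1)
print(f"regression-pipeline rho = {est['corrected']:.3f} "
      f"(95% CI {est['ci_low']:.3f}-{est['ci_high']:.3f})")
```

prints

```
dLV = 0.989   dLA = 0.800   dN = 0.824
sigma = 0.493   epsilon = 0.448
subspace correlation rho = 0.591
predicted binding error        = 0.0296
predicted generalization error = 0.2331
regression-pipeline rho = 0.591 (95% CI 0.518-0.675)
```

The 120-neuron synthetic session was built with `dLV = 1.0, dLA = 0.8,
dN = 0.8, sigma = 0.5` (true `rho = 0.61`): the crossnobis/NNLS decomposition
recovers the geometry to a few percent, and the predicted error rates say
this code misbinds on ~3% of two-offer trials while a value decoder trained
on one side generalizes to the other with ~77% accuracy.  The independent
regression-based subspace pipeline lands on the same correlation.

A thin CLI mirrors the library (`bindgeom synth`, `bindgeom decompose`,
`bindgeom simulate`, `bindgeom fit-behavior`, `bindgeom subspace`,
`bindgeom decode`), exchanging CSV tables with JSON metadata sidecars; see
`bindgeom --help`.

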