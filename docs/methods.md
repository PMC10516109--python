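# Methods

## The linear–nonlinear code and its error rates

A stimulus is a point on a `K`-dimensional lattice with `n` levels per
feature.  Its population representation is the sum of a linear part —
`L x_z`, with one orthogonal column per feature and centered, unit-spacing
integer coding `x_z` (so the column norm *is* the distance between adjacent
stimuli; a variance-1 coding would break the identity `r(x21) − r(x11) =
dLV·L1` that everything downstream relies on) — and a conjunctive part: one
orthogonal column of length `m` per lattice point, active only for that
stimulus.  Two conventions worth stating explicitly because they are easy to
get wrong by a factor of √2:

* the pairwise **nonlinear distance** is `dN = √2·m` (two orthogonal
  length-`m` columns switch between any two stimuli);
* the **chimera distance** between a two-stimulus set and its misbound
  partner is `dS = |M1 + M2 − M3 − M4|·m = 2m = √2·dN` (the linear parts
  cancel exactly).

All distances are derived from explicitly constructed columns rather than
quoted constants; `code_simulator.build_code` orthogonalizes `L` and `M`
exactly (QR), so the identities hold to machine precision at any `N` instead
of only in the large-`N` random-vector limit.

Error rates use the standard normal CDF `Q(·)` evaluated at negative
arguments:

* overall: `N_C·Q(−d_C/2σ) + N_{C+1}·Q(−d_{C+1}/2σ)`, clipped to
  `[0, 1 − 1/n^K]`;
* misbinding: `N_S·Q(−d_S/2σ)`, equal to the chance level `N_S/2` at
  `dN = 0`;
* generalization (prototype decoder): `Q(−(1/σ)·dLV²/(2√(dLV²+dNε²)))` with
  `dNε² = dN² + ε²`.

Neighbour counts (`N_LA`, `N_LD`) and the chimera count `N_S` are computed by
exhaustive lattice enumeration (cached); `N_S` averages over **ordered
stimulus draws with replacement**, which gives the reference value `1/4` for
the 2×2 task with two stimuli (unordered-distinct averaging would give 1/3).
A chimera is defined operationally: a different multiset of stimuli with the
same per-feature sums, i.e. indistinguishable to the purely linear code.

### Regime of validity of the union bound

The union bound over-counts overlapping error events, so its slack grows
with the error rate itself.  Measured against exact maximum-likelihood
decoding, the overall-rate formula is accurate to better than 0.02 as long
as the predicted rate stays below ≈ 0.13; at `σ = d_C/2` the slack reaches
0.04–0.08.  The default validation grid is therefore `dLV = dLA = 1`,
`dN ∈ {0.5, 1, 1.5}`, `σ ∈ {0.2, 0.25, 0.3, 0.35}`.  Likewise, the
misbinding formula describes the pairwise event "a chimera is preferred to
the truth"; the frequency with which the *full* decoder's final answer is a
chimera runs lower when overall errors are common, because competing wrong
sets absorb those trials.  Empirical validation
(`measure_binding_rate(mode="preferred")`) measures the pairwise event,
which is also exactly invariant to `dLV` and `dLA`.

### Continuous case

Two continuously valued offers encoded by unit columns at angle `θ`
(subspace correlation `cos θ`) are recovered by inverting the 2×2 encoding
matrix; the total estimator variance is `2σ²/sin²θ`, checked against
Monte-Carlo decoding at three `(θ, σ)` points.

## Estimation pipeline

**Crossnobis distances.**  Trials are split into 5 stratified, seeded folds;
the squared distance between conditions is the mean over ordered fold pairs
of the inner product of fold-wise mean differences.  Independent fold noise
makes the estimator unbiased (entries may be negative; they are passed to
the decomposition unclipped).  No noise-whitening is applied.  Bootstrap
uncertainty resamples trials **within** folds — resampling across fold
boundaries would let duplicated trials share noise between folds and
reintroduce exactly the bias the estimator removes (we measured a spurious
upward shift of ~0.1 squared units on null contrasts before adopting this
scheme).

**Decomposition.**  For the four value × side (or value × order) conditions,
the six pairwise squared distances satisfy `d² = A·[dLV², dLA², m²]` with
rows `[1,0,2]`, `[0,1,2]`, `[1,1,2]` (every pair differs by two orthogonal
conjunctive columns, hence the constant 2).  The system is solved by
non-negative least squares; the reported nonlinear distance is `dN = √2·m`.

**Noise and standard-error distance.**  `σ` is the s.d. of single-trial
residual projections onto the unit vector joining the two training-condition
centroids, pooled across conditions — the noise component that matters for
the value decoder.  `ε` is the *full-space* standard-error distance of the
two training centroids, `ε² = Σ_c Σ_i var_i(c)/n_c`: a centroid estimated
from finitely many trials is displaced by a random vector of about this
length, which degrades generalization exactly like an extra conjunctive
perturbation, so it enters in quadrature with `dN`.  (A projected-variance
convention underestimates this by ≈ √N and visibly underpredicts the error
of a prototype decoder trained on estimated centroids.)

**Subspace vectors and the noise ceiling.**  Per-neuron value vectors come
from the interaction regression (`value` min–max normalized, `side`
effects-coded ±1): `w = βValue + side·βInteraction`; intercept and pure-side
terms cancel.  Raw correlations between estimated vectors are attenuated by
coefficient noise, so both the hypothesis test and the estimator are built
on **disjoint trial half-splits** (within condition strata, resampled within
halves): the observed statistic is the cross-context, cross-half
correlation; the ceiling is the geometric mean of the two contexts'
same-context cross-half reliabilities.  Under a truly shared subspace both
have the same attenuation in expectation, so the paired one-sided p-value
(with the +1 small-sample correction) is calibrated — we verified ≥ 90%
non-rejection on generatively parallel populations, where a
bootstrap-resample ceiling (which shares the single sample's noise between
its halves) falsely rejected two-thirds of the time.  Dividing observed by
ceiling gives the classic disattenuated correlation estimate, whose
bootstrap distribution supplies the CI used for recovery scoring.

**Decoding.**  Pseudopopulations resample trials within matched conditions
across sessions (inclusion thresholds 160/80 trials per condition for
broad/narrow splits).  Preprocessing is z-score + PCA retaining 99% variance,
fit on training data only.  The classifier is a linear soft-margin SVM whose
regularization constant defaults to `1/n_train`: scikit-learn sums hinge
losses, so a constant `C` means vanishing regularization as trials grow, and
with trials comparable to features an under-regularized margin overfits
noise directions and stops reflecting the representational geometry (we
measured a 0.05–0.09 inflation of generalization error against the
geometry-based prediction at `C = 1`).  The constant remains exposed.
Standard accuracy averages ten 10% holdouts; generalization accuracy uses
every trial of the held-out context.

**Error-trial projections.**  Spatial ("left offer higher" vs "right offer
higher") and temporal ("first higher" vs "second higher") decoders are
trained only on optimal-choice trials; projections are signed distances to
the boundary normalized by the weight norm, flipped so positive means
"toward the correct class", and compared between held-out optimal and
suboptimal trials by a one-sided paired t-test across sessions.

## Behavioral model

`SV(p, s) = w(p)·s^γ` with the Prelec warp `w(p) = exp(−β(−ln p)^α)` and a
softmax on `SV₁ − SV₂`.  The default fitted warp is the one-parameter form
(β ≡ 1): at session-scale trial counts the two-parameter warp trades `α` off
against `β` and the temperature (the profile likelihood is flat over
`α ± 0.1` at 5000 trials), so its parameters are not individually
recoverable; the two-parameter form stays available via `prelec="two"`.
Fitting is multi-start L-BFGS maximum likelihood; the four model variants
(objective / utility-only / probability-only / full) are compared by BIC,
which ranks nested softmax models equivalently to the usual
free-energy-based selection at these scales.  Value binarization takes the
35th/65th percentiles (linear interpolation), excluding the middle band,
ties excluded.

## Synthetic data

The task generator draws offer pairs (medium/large/safe at
43.75/43.75/12.5%, stakes 0.165/0.240/0.125 mL, win probability uniform on
[0, 1], safe offers certain), randomizes sides and order, and flags safe
trials for exclusion.  The default agent is risk-seeking (`γ = 1.3`,
`α = 0.7`, `β = 1`) with temperature 58, calibrated by forward simulation so
it picks its higher-valued offer on ≈ 82% of risky trials — a realistic
performance level for this task family.

`generate_population_session` composes an 11-column orthonormal basis:
shared value axis (`dLV`), side and order axes (`dLA_space`, `dLA_time`),
and four conjunctive columns each for value-level × side and value-level ×
order.  Continuous subjective value drives the linear part, scaled so the
median-split level centroids sit exactly `dLV` apart (keeping the discrete
theory's ground truth well defined); the conjunctive part uses the binarized
levels, mirroring how the analyses move between the continuous task variable
and the discrete theory.  Three windows are emitted per trial: first offer
alone, second offer alone, and both offers together; the eight
order × value conditions label the joint window.  An optional planted effect
adds a configurable fraction of the spatial-swap vector (the exact chimera
direction) to suboptimal-choice trials, giving the error-trial projection
analysis a known positive control.  Per-neuron gain heterogeneity is a free
knob (default off; recovery degrades gracefully as it grows).  All
generators are pure functions of their seeds, and session metadata records
every ground-truth quantity the recovery battery scores.

What the generator does **not** emulate: Poisson spiking or any
non-Gaussian/correlated noise, within-trial dynamics, session-to-session
drift, eye movements, and tuning curve shapes beyond the
linear-plus-conjunctive form.  Passing tests therefore demonstrate that the
estimators are correct and calibrated under the theory's own noise model,
not that real recordings satisfy that model.

## Problem sizes and defaults

Default analyses use 5 crossnobis folds, 200 bootstrap resamples, 1000
permutations (ANOVA) and 1000 noise-ceiling iterations; the test suite and
the acceptance script scale these to 100–500 iterations and use
10⁴–10⁵-trial simulations, 20-session planted-effect batteries, and a
200-neuron × 500-trials/condition recovery session — sizes chosen so the
whole battery runs in minutes on one CPU while keeping Monte-Carlo standard
errors well below the tolerances being checked.

## Known limitations

* The union-bound rates are small-error-rate approximations (see above);
  they are reported clipped at chance but are not sharp near chance.
* The overall-rate formula assumes a symmetric lattice spacing
  (`dLA = dLV`); misbinding and generalization rates do not.
* The ε convention treats centroid error as isotropic in the response
  space; strongly anisotropic noise would need the whitened (Mahalanobis)
  variant, which is deliberately out of scope.
* NNLS point estimates at the non-negativity boundary (`m² = 0`) are biased
  upward for truly linear codes; the bootstrap distribution makes this
  visible.
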