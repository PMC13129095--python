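# Methods

## The model

`predinet` simulates rate networks of `N` recurrently connected neurons that
perform predictive processing of `P` paired multimodal inputs (for example a
sound and the movement that produces it).  The presence of pair `k`'s
components is encoded by amplitudes `x_k, y_k ∈ {0, 1}`; each component
enters through an N-dimensional feedforward weight vector (`w^k` for the x
modality, `v^k` for y).  The voltage dynamics are (time in units of the
membrane constant)

    dh/dt = −h + b ( J φ(h) + I^F ),      r = φ(h) = max(h − θ, 0),

with the prescribed connectivity and input

    J   = −(1/N) (W Wᵀ + V Vᵀ),
    I^F = W x + V y.

Associative learning is summarized by a single dial per pair: the
within-pair weight correlation `μ^k ∈ [0, 1]` (0 untrained, →1 fully
learned; `μ = 0.97` is used as the after-training value when fitting data).
Weights are sampled i.i.d. Gaussian with zero mean, unit variance, and
correlation `μ^k` between `w_i^k` and `v_i^k`; distinct pairs are
independent.  Weights are a *dial*, not a trained quantity: there is no
online learning in the package.

**Normative interpretation.**  With the linear readouts
`x̂^k = w^k·r/N`, `ŷ^k = v^k·r/N` (the network's internal predictions), the
fixed point of the dynamics is exactly the minimizer over `r ≥ 0` of the
convex objective

    E(r) = Σ_k [ (x^k − x̂^k)² + (y^k − ŷ^k)² ]  +  (2/(bN)) Σ_i F(r_i),
    F(r) = (r + θ)²/2,

i.e. squared multimodal prediction errors plus an encoding-efficiency
penalty whose weight is the inverse gain.  The efficiency term is written
*intensively* (per neuron, note the 1/N): this is the unique normalization
under which the stated connectivity/input convention is the exact gradient
flow of the objective with O(1) rates and O(1) predictions in the large-N
limit, and it is the convention that reproduces the closed-form
voltage-variance ratio below in direct simulation.  The dynamics decrease
`E` monotonically; because `E` is strictly convex for `b > 0`, the steady
state is unique and independent of initialization.  Both facts are enforced
by tests.

Stimuli are treated as quasi-static: the prediction delay of the underlying
objective is not modeled, and steady-state analyses assume inputs constant
on the timescale of the rate dynamics.  Conditions for pair `k` are
`match` (x_k = y_k = 1), `x_only` / `y_only` mismatches, and `cross_pair`
controls (x_k together with the y of a different pair).

## Numerical methods

*Steady states.*  The fixed point is the solution of a strictly convex
quadratic program over `r ≥ 0`.  The solver runs a damped Picard warmup
(spectrally safe step `γ = 1/(1 + b·λ_max(−J))`) to identify the active set,
then active-set Newton steps that solve the linear fixed point on the
trial set exactly — via a Woodbury identity in the 2P-dimensional weight
space when `2P` is small, or by conjugate gradients for high-dimensional
stimulus ensembles.  Fallbacks are L-BFGS-B minimization of the objective
followed by one Newton polish, then a long damped iteration.  The residual
tolerance (default `1e−10` on `max_i |−h_i + b(Jr + I^F)_i|`) is scaled by
`max(1, b·max|I^F|)` because absolute residuals below machine precision
relative to the drive are unattainable in float64 at data-constrained gains
(`b ≈ 170`).  Connectivity products use the low-rank factorization
`Jr = −U(Uᵀr)/N`, `U = [W V]`, so no N×N matrix is materialized unless the
network has been pruned.

*Integration.*  Explicit Euler with default `dt = 0.01`, capped at 90% of
the stability bound `1/(1 + b·λ_max(−J))`; an explicitly requested unstable
step raises an error, as does divergence.

*Self-couplings.*  The diagonal of the Gram construction is kept (the
construction gives no reason to exclude it); `exclude_diagonal` is a
parameter defaulting to `False`.

*Pruning.*  Random synapse removal with survivor rescaling `1/keep_prob`
breaks the symmetry of `J`; pruned networks need not admit a fixed point
(they can sustain activity fluctuations), so their analyses run on
simulated trajectories and `steady_state` raises if its asymmetric solve
fails to converge.

## Balance observables

The balance level of neuron i at steady state is
`B_i = |I^F_i / (I^F_i − I^R_i)|` with `I^R = −(Jr)`; since
`h = b(I^F − I^R)` at steady state, `B_i = |b·I^F_i / h_i|`.  The
time-resolved form `B_i(t) = |b·I^F_i(t)/h_i(t)|` coincides with the static
definition at steady state; it is reported only where `|h_i| > 10⁻⁸`, and
neurons with near-zero net input are flagged rather than dropped.  Large B
means tight balance (recurrent prediction nearly cancels the input).

For `P = 1`, `θ = 0` the mismatch/match ratio of voltage variances has the
closed form

    σ²_mism/σ²_match = (1/2) [μ² + (1−μ²)(1+b/2)²]
                       / [μ² + μ + (1−μ²)(1 + b + (1−μ)b²/4)],

equal to 1/2 at μ=0 and 1/4 at μ=1 for every b.  `variance_ratio` evaluates
it, `invert_variance_ratio` solves it for b by bracketed root search
(reporting non-identifiability at μ=0 and unattainable ratios explicitly).
A Monte-Carlo test at `N = 10⁴` verifies the formula against direct
simulation across a (b, μ) grid.

**Data-constrained gain.**  In the match condition at `P = 1` the voltage is
exactly proportional to `w + v`, so the balance level is the same for every
neuron and the median is sharp.  The intracellular estimate
`B* = 162` is therefore interpreted as the match-condition median;
`calibrate_gain_to_balance` inverts the monotone map `b ↦ median B` on an
actual sampled network, giving `b* ≈ 174` at `N = 2000` (the analytic
large-N value is `1 + b(1+μ)/2`, i.e. `b* ≈ 163`; the finite-N calibration
is used throughout because analyses run at finite N).  `optimal_gain`
implements the constrained procedure (smallest gain whose mean mismatch rate
clears a floor, which also minimizes the match rate, both being increasing
in b); the floor is an artifact parameter fixed once, at α ≈ 0, so that the
resulting `B*` equals 162.  With that floor the optimal balance `B*(α)`
decreases with the stimulus load `α = P/N` — loose balance limits the
interference between many learned predictions.  At `α = 0.5` the floor is
not attainable at any gain (the mismatch mean rate saturates below it in
direct simulation), so the default α grid for this analysis stops at 0.3;
the sweep raises an explicit infeasibility error beyond it.

## Functional cell types and desegregation

With `h^x` (x-only), `h^xy` (match) and scale σ (the standard deviation of
the x-only voltage distribution after learning, computed on a μ=0.97
network of the same size, gain and seed, and reused across learning
stages): a neuron is a representation (R) cell if `h^x > σ/2` and
`|h^x − h^xy| < σ/2`, and a (positive) prediction-error (PE) cell if
`h^x > σ/2` and `h^x − h^xy > σ/2`.  The two criteria are mutually
exclusive.  Voltages are centered before classification for `α > 0` and for
inhibitory populations (their means are not zero); at `α ≈ 0` the raw
voltages are used.  The mirrored (negative-PE) criterion is available
separately; in this binary one-to-one design it coincides with the positive
criterion applied to the y stimulus and is excluded from headline PE
fractions.

A neuron is *responsive* to a pair when it passes the `h^x > σ/2` gate;
*mixed-representation* neurons are responsive to both pairs of a pair of
associations and classified R for one but PE for the other;
*dedicated-PE* neurons are PE for at least one pair and never R for any
pair they respond to (an operational definition; with many pairs the
evaluation may be restricted to a stated subset).  At the data-constrained
gain and `α ≈ 0` about 25% of dually responsive neurons are mixed.

Mixing versus stimulus dimension is evaluated at the fixed data-constrained
gain.  In direct simulation the mixed fraction rises from ~25% to ~43–45%
around `α = 0.2–0.3` and then falls at `α = 0.5`, where match suppression
itself breaks down at this gain; because functional labels are essentially
independent across pairs, the fraction is bounded by `2p(1−p) ≤ 1/2`, so
the attainable growth ratio tops out just under 2.  This is a known,
documented divergence from mean-field treatments of the same quantity.

## Decoders

`build_decode_dataset` builds balanced match/mismatch trial sets from
steady-state rates (or raw stimulus vectors).  Trial noise is applied to
the *stimulus amplitudes* by default and passed through the network
(`noise_model='input'`); additive feature noise is available.  Mismatch
trials may be single-component presentations and/or cross-pair controls.
The cross-pair design equates the number of active components per class,
which provably removes any linear signal from the raw inputs (a generalized
XOR), and — before learning — makes the population mean rate uninformative.
After learning only the matched (associated) condition is suppressed, so a
one-dimensional mean-rate threshold matches the max-margin decoder
(`LinearSVC`, L2, C selected by 5-fold cross-validation on the training
split; errors reported as mean ± SD over 10 split repeats).  The mean-rate
decoder, being stimulus-independent, transfers across pairs without
retraining; the max-margin decoder may latch onto pair-specific directions
and is not expected to transfer.

## Excitatory/inhibitory decomposition

The single-population model is embedded in a Dale-compliant E/I network
with `φ_I = ReLU(0)`, `τ_I = 0.5`, `J^II = 0` and matching constraints
`J^EE − J^EI J^IE = bJ`, `I^E − J^EI I^I = b I^F` (inhibitory matrices
stored as magnitudes).  The one-parameter family is realized as
*per-I-neuron mixing*: row i of `J^IE` is `(1−λ)e_i + λ p_{k(i)}`, where the
prediction channels `p` are nonnegatively shifted weight vectors
`(w + max|w|·1)/N` (two per pair) plus one global channel, assigned to I
neurons round-robin; `N_I = N_E` at every λ.  `J^EI` combines the rectified
negative part of `bJ` with matched channel columns, scaled by
`s(λ) = 1/((1−λ)² + λ²)` so that `J^EE = bJ + J^EI J^IE` is entrywise
nonnegative — the constraints then hold *identically* (zero residual by
construction), and the E steady state equals the original network exactly,
which the tests verify by re-solving from the E/I blocks alone.  At λ=0
each I neuron copies its parent E neuron; at λ=1 every I rate is an exact
linear function of one internal prediction and the population mean rate.
The channel normalization is a free parameter of the family (it cancels in
the product); it is fixed so that the across-neuron variance of the channel
rates matches the private-copy variance in a reference condition, which
spreads the private→prediction transition over the whole λ range and makes
λ identifiable from fast-spiking population correlations.
`estimate_lambda` matches the four movement/passive correlations (RS/FS ×
expected/probe) against model curves on a λ grid.

Known limitations of this realization: the before-learning decrease of FS
alignment with λ, and the sparsification/depression of I→E weights during
learning at λ = 0.6, are properties of a different (unavailable)
parameterization of the family and are not reproduced; at λ = 0 the I→E
weight distribution does broaden with learning, as expected from the
growing magnitude of the rectified Gram entries.

## Hierarchical variant

Three modules: M1 receives x, M3 receives y, M2 sits between.  Modules
exchange P-dimensional codes (module l sends `V^lᵀr^l/N` upward and
`W^lᵀr^l/N` downward), so inter-module couplings are the rank-P composites
`V^l W^{l+1,T}/N` and every input stays O(1).  The bidirectional dynamics
are the exact gradient flow of the stacked objective

    |x − d¹|² + |u¹ − d²|² + |u² − d³|² + |u³ − y|² + Σ_l (2/(b_l N)) Σ_i F,

and the joint steady state is computed by block-coordinate exact
minimization (provably convergent, being alternating minimization of a
jointly convex function).  The unidirectional control lets only M2 predict
its neighbours' activity; embedding those predictions back into neuron
space yields the documented `−δ_ij` self-terms and removes the V-Gram from
M1/M3.  Learning (μ) applies within every module's (W, V) pair by default;
per-module μ values allow confining it to one interface.  Gains are
calibrated by the floor-plus-PE-fraction procedure (`calibrate_gains`); the
package default `(b₁, b₂, b₃) = (20, 120, 20)` was chosen that way and
yields the maximal mismatch/match ratio and PE fraction in M2 after
learning, and cross-modal stimulus information in M3 only in the
bidirectional mode.

## Transient protocols

Pulse protocols (default width 0.1, amplitude 1) present x and, in the
match condition, y lagged by `Δt`; metrics are computed in the declared
post-removal window `[offset + 0.5, offset + 3]` (the window is a package
default, not a literature value): the mismatch/match rate ratio, an
exponential decay timescale (least-squares on log mean rate, floored at
`10⁻⁶`), and the norm of the condition-difference rate vector.  Note the
connectivity is negative semidefinite, so no linear mode decays slower than
the membrane constant; learning slows the *effective* decay by moving
response energy into the near-zero (w−v) eigenmode, so fitted timescales
approach 1 from below.  Step protocols keep the drive on and report the
median time-resolved balance; after learning the onset of the predicted
second stimulus produces a transient balance peak, which decreases with α.
Time-resolved classification applies the static criteria per time point
with a fixed σ and converges to the static labels for sustained inputs.

## Synthetic recordings

All generators produce trials × neurons × 10-ms-bin arrays with serialized
ground truth, and every downstream fit is validated by parameter recovery:

* **Voltage (V-M style):** 32 neurons, match window −0.1–0 s and mismatch
  window 0–0.1 s around a decoupling event; trial noise is i.i.d. Gaussian
  with default sd 0.2× the population response sd.  The fit draws 50 voltage
  samples per window, squares the std ratio, and inverts the closed form;
  repeats combine a neuron-level (cluster) bootstrap with fresh 50-sample
  draws so the CI reflects both the small neuron count and the sampling
  rule.
* **Rate (A-M style):** baseline −0.1–0 s at a constant spontaneous rate,
  evoked 0–0.06 s; passive trials carry the x-only response, movement trials
  the match response.  The fit resamples 400 per-neuron rate changes with
  replacement and inverts the squared mean-change ratio (for ReLU with
  centered Gaussian voltages the mean rate is proportional to the voltage
  std).
* **Probe ensembles:** untrained probe sounds enter through
  `w_p = ρ·w_e + √(1−ρ²)·ξ`, so the construction overlap ρ dials the
  representation similarity.  Active trials pair the sound with the trained
  movement, whose response is present in the *baseline* window as well, so
  response changes cancel the shared motor component as the experimental
  windows do.  An optional sparsity target sets θ from the quantile of the
  threshold-free passive voltage distribution.  A separately constructed,
  explicitly synthetic *segregated null* (shared Δ-sign pattern across
  stimuli) yields segregation index 1 and is the contrast for the model's
  index < 1.
* **RS/FS recordings:** RS rows sample E rates, FS rows the I rates of an
  E/I decomposition; pair 0 is the trained association, pair 1 an untrained
  probe; movement trials pair each sound with the trained movement.

What these generators do *not* emulate: correlated trial noise, spiking
variability, adaptation, realistic tuning curves, and session-level
heterogeneity.  Passing recovery tests therefore demonstrates the
correctness and internal consistency of the analysis pipelines, not their
robustness to real-data nuisance structure.

## Default problem sizes

Analyses ship with desk-scale defaults chosen to keep full runs in minutes
on one CPU while staying in the self-averaging regime: N = 2000–4000 for
population statistics and calibration, N = 10⁴ for the Monte-Carlo check of
the closed form, N = 400–800 for E/I, decoding and hierarchical analyses,
50 replicates for recovery studies.  Every stochastic operation takes an
explicit seed, and CLI runs record all seeds in a JSON manifest.
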