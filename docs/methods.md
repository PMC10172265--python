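# Methods

This note documents the models, numerical choices and limitations behind
`spinecreep`, in the package's own terms.

## Loop parameterization and fitting

Each hysteresis branch is the modified double Boltzmann sigmoid
`RoM(m) = A/(1+e^{a₁(m−m₁)}) − B/(1+e^{a₂(m−m₂)}) + B`.  *A* and *B* are
**defined** as the minimum and maximum of the sampled RoM and are fixed
before optimization; only the four shape parameters per branch are free.
Fitting uses bounded multi-start nonlinear least squares
(`scipy.optimize.least_squares`): starts at slopes {0.5, 1, 2} /Nm crossed
with centers {−2, 0, 2} Nm, slopes constrained positive, tolerances 1e-10,
at most 5000 residual evaluations per start; the lowest-cost solution wins.
The two branches are fitted independently with the shared A, B; the
acceptance gate uses the R² pooled over both branches (per-branch values are
also reported).  Loops are split into branches by the local sweep direction
of the moment signal; the branch with the larger mean RoM over the common
moment range is the upper one, with ties broken by acquisition order.

Numerical notes:

* the logistic exponent is clamped at ±700, which only matters for
  unphysically steep slopes and prevents overflow;
* a flat loop (zero RoM span) makes the shape unidentifiable and raises a
  degenerate-loop error, as does a loop with a single sweep direction;
* because the sigmoid never attains its asymptotes on the bounded ±7.5 Nm
  interval, the sampled extrema sit slightly inside the generating A, B.
  Consequently parameter recovery from parametric loops is exact only up to
  this asymptote tail.  Refitting a fitted curve reproduces the *curve* to
  better than 1e-6 of the loop span; the *parameters* of one branch can move
  by up to ~1e-3 relative for shallow slopes.  The fit benchmarks therefore
  draw slopes in 2.0–3.0 /Nm with centers within ±1.2 Nm, where the tail is
  negligible and shape recovery is better than 1e-3.

## Creep statistics

Absolute RoM of a cycle is the fitted upper-branch value at +7.5 Nm, which
makes every ratio computable from the 10 parameters alone.  `r_load` divides
the 3rd-cycle RoM by the last-cycle RoM of a block; `r_break` divides the
last pre-break RoM by the third post-break RoM.  Kendall τ-b (tie-corrected,
via scipy) correlates r_load with total testing time; two correlations are
compared by Fisher's transformation z = artanh(τ) with variance 1/(n−3) per
group and a two-sided normal test.  Wilcoxon signed-rank, Mann–Whitney U and
Shapiro–Wilk delegate to scipy's reference implementations; all tests are
two-sided at α = 0.05 and no multiplicity correction is applied.  RoM
progressions are normalized to the third cycle of the first block of their
direction.

## Synthetic generator

The generator emulates the statistical signatures of an 18-hour cadaver
session: per specimen, three loading directions (flexion–extension FE,
lateral bending LB, axial rotation AR; base loop amplitudes 6.5°, 5.0°,
2.5°), six 30-minute blocks per direction (~20 cycles for FE/LB, ~60 for AR)
separated by 15-minute breaks, with block start times FE 0 h, AR +1 h,
LB +2 h repeating every 3 h.

Creep acts multiplicatively on the loop envelope B−A about its midpoint.  At
cycle k of block s the envelope factor is

    Q_s · [1 + c_s (1 − e^{−κ(k−3)})],   c_s = c0 · d_s · (specimen/block jitter)

anchored so the multiplier is exactly 1 at cycle 3 (the r_load reference
cycle), with saturation rate κ = 0.4 /cycle.  The block decay is an
exponential approach to a floor, `d_s = f + (1−f) e^{−λ(s−1)}`; a linear law
is available via `decay_mode="linear"`.  Breaks remove the fraction ρ of the
growth accumulated during the block; the remainder carries into Q_{s+1}, so
the segment never returns to its original state within a session.

The per-temperature calibration shipped as the default —

| group | creep gain c0 | decay floor f | decay rate λ | recovery ρ |
|-------|---------------|---------------|--------------|------------|
| BT    | 0.08573       | 0.610         | 0.310        | 0.412      |
| RT    | 0.05655       | 0.868         | 0.300        | 0.403      |

— was fixed once, by matching large-sample medians of the generator to the
reference experiment's printed group medians (r_load BT 0.9351 / RT 0.9492,
r_break BT 1.0275 / RT 1.0209, sixth-block pooled r_load 0.9471, first-block
FE increase 8.74 % at BT).  Those printed medians come from a small sample
(three specimens per group) and are not jointly consistent with a creep
decay that is everywhere weaker at RT: the RT overall median exceeds the
pooled sixth-block median.  The calibration resolves this by letting the two
groups converge toward similar sixth-block levels (BT ≈ 0.943, RT ≈ 0.951),
whose pooled median reproduces 0.9471.  A linear block decay cannot satisfy
all five medians simultaneously, which is why the floor-exponential is the
default.

Random effects: specimen amplitude 10 % lognormal, specimen slopes 5 %
lognormal, specimen center shift 0.1 Nm; creep-gain jitter 7 % per specimen
plus 3.5 % per block; block-level slope jitter 2 %.  Per-cycle perturbations
(slopes 0.05 %, centers 0.002 Nm, extrema 0.01°) represent the residual
uncertainty of extracting parameters from clean laboratory signals and are
deliberately small next to the specimen-level variability, so that the
cycle-to-cycle evolution within a block is essentially the systematic creep
trajectory.  Sagittal symmetry doubles the LB and AR data through the exact
point mirror RoM′(m) = −RoM(−m), whose closed-form parameter map
(A′ = −B, B′ = −A, branches exchanged with (a₁′,m₁′,a₂′,m₂′) = (a₂,−m₂,a₁,−m₁))
is verified against sampled mirrors in the tests.  The default dataset is
3 BT + 3 RT specimens × 3 directions × 6 blocks + flips = 180 sequences,
split 116 train / 9 validation / 55 test by a seeded shuffle of whole
sequences; the first cycle of every block is dropped as preconditioning.

What the generator does **not** model: continuum disc mechanics, osmotic or
temperature physics, tissue degradation over the session, direction-specific
creep differences, asymmetric (mid-shifted) loops, and measurement artifacts
of motion tracking.  Passing tests therefore demonstrate that the analysis
pipeline recovers the statistical structure it assumes, not that the
generator is a faithful tissue model.

## Feature scaling

Every feature (τ_t plus the 10 parameters) is mapped linearly to [−1, 1]
using the midpoint and half-range of its training-split values; constant
features get a half-range of 1 with a warning.  The scaler is fitted on the
training split only, to keep test information out of the model; fitting on
all data can be reproduced by passing a pre-fitted scaler.  Masked padding
positions are exactly 0 after scaling.  Values outside the fitted range at
prediction time extrapolate outside [−1, 1] with a warning rather than an
error.

## Surrogate network

Stacked LSTM layers (gates with sigmoid activation, tanh candidate, cell
update c = g_f⊙c_prev + g_i⊙c̄, hidden state h = g_o⊙tanh c, output = h)
followed by one linear dense layer mapping each timestep's hidden vector to
the 10 curve parameters.  The cell, batched forward pass, backpropagation
through time and Adam are implemented in numpy (float64, Glorot-uniform
initialization, unit forget bias); analytic gradients are verified against
numeric differentiation in the tests.

Input layout: the 11-vector (τ_t, 2nd-cycle parameters) is repeated at every
timestep and the output at step j is the parameter vector of cycle j+2, so
the recurrent state unrolls the creep trajectory from a static description
of the segment.  A teacher-forcing layout (step input = previous cycle,
autoregressive prediction) is available via `input_layout="teacher"`.  τ_t
is the per-temperature-group Kendall τ between r_load and total testing
time, multiplied by the block's start hour, constant along a sequence.

Loss: per sequence, the mean over its real timesteps of the squared error
norm summed over the 10 outputs; then the mean over sequences.  Padded
timesteps carry zeros and are excluded by the mask, which makes the loss and
all gradients exactly independent of padding length.

Training: Adam with optional exponential learning-rate decay and global
gradient-norm clipping (default norm 1.0, which tames the occasional loss
surge of small-batch training), seeded shuffling and dropout (applied to
layer outputs between stacked layers).  Stopping is dual: target training
loss 5×10⁻⁴, or a patience rule that fires when neither the training- nor
the validation-loss moving average (window = patience = 50 epochs) has
improved within the window, or the epoch cap.  The patience rule requires
validation data; training without a validation split stops on the target or
the cap alone.  With few validation sequences the validation loss is noisy
and can plateau while the training loss still converges, so benchmark runs
that target the training loss are best made without a validation split.

Two configurations ship:

* `SurrogateConfig.reference()` — 6 LSTM layers [64, 64, 128, 128, 256,
  256], dropout 0.15, learning rate 1e-3, batch size 324 (larger than the
  training set, i.e. full-batch updates), cap 44 753 epochs.  This is the
  full-scale configuration of the original study; training it on a single
  CPU takes days and is not part of the automated suite.
* `SurrogateConfig.desk()` — 2 layers [32, 64] (~31 k parameters), batch
  size 16, learning rate 3e-3 with 0.9995/epoch decay, gradient clipping at
  norm 1.0, cap 3000 epochs.  Sized so that the 116-sequence default dataset
  reaches the 5×10⁻⁴ target in minutes on one CPU.

Predicted parameter vectors occasionally invert the envelope (A > B);
`predict_sequence` swaps the pair and counts the repair
(`n_envelope_violations_`), while `predict_array` returns the raw values.
Prediction quality is summarized as the mean pooled-branch curve R² between
predicted and true cycles reconstructed on a 101-point moment grid.

## Design choices that were genuinely open

* The printed cell-update equation indexes the candidate with the previous
  step; the standard current-step candidate is used, matching the cell
  diagram and every mainstream implementation.
* The published split sizes (116/64/9) sum to more than the published
  sequence count (179); the package honors 116 train / 9 validation and
  assigns the remainder to test.
* Whether the published single R² per fit is per-branch or pooled is
  unstated; pooled is the default and per-branch values are exposed.
* The Fisher-comparison variance is the classical 1/(n−3); the per-group
  pair count entering it is configurable because the original pairing is
  unstated.
* Batch size 324 with 116 training sequences is interpreted as full-batch
  training.

## Limitations

The surrogate is validated on synthetic data only; its 0.99+ validation
curve R² reflects the generator's smooth creep law and modest noise, and
real cadaver data with richer inter-specimen variability will be harder.
The calibration reproduces group medians, not distributions or covariances.
The masked loss assumes trailing padding (variable-length sequences padded
at the end), not gaps.  Training beyond ~10⁵ parameters is impractical in
this pure-numpy implementation.
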