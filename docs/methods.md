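# Methods

## The adversarial game on the conditional factor

The package assumes two pre-trained players: a conditional counterfactual
generator `G(x, a)` that re-synthesises image `x` at target age `a` while
preserving subject identity and diagnosis, and a binary classifier `C(x)`
returning p(AD).  The per-sample loss on a counterfactual is the binary
cross-entropy `L_i(a_i) = L_s(C(G(x_i, a_i)), y_i)` against the *source*
label `y_i` — the label-preservation assumption: moving a brain along the
ageing axis does not change its diagnosis.  The game alternates

* **ascent**: `a_i ← clip(a_i + γ_a · dL_i/da_i, 60, 90)` for every sample
  in a fixed hard set `D_hard` (the N training samples with the highest
  loss, selected once before the loop; ties break by sample id so selection
  is reproducible), and
* **descent**: one epoch of cross-entropy minimisation of `C` on
  `D_train ∪ D_syn`, where `D_syn = {G(x_i, a_i)}` carries the source
  labels.

Retraining on the union rather than on `D_syn` alone is what keeps the
classifier from forgetting the original data distribution; the
memory-buffer variant replaces `D_train` with a uniformly sampled `M%`
subset `D_store` everywhere (selection, synthesis, updates), so at
`M = 100` the two loops coincide bitwise under the same seed.

The gradient `dL_i/da_i` is an exact chain-rule product, not a finite
difference: the classifier supplies `∂L_i/∂image` by backpropagation to its
input, the generator supplies `∂image/∂a_i` (analytically for the
simulator, through the Fourier encoder for the neural generator), and the
two are contracted pixelwise.

## Fourier conditioning

Conditions `v = (age, diagnosis)` are normalised into the half-open unit
square — age affinely with an `ε = 1e-6` slack in the denominator so the
upper bound maps strictly below 1, diagnosis to {0, 0.5} — and encoded as
interleaved cosine/sine pairs `p_j cos(2π b_jᵀ v), p_j sin(2π b_jᵀ v)`,
`j = 1..m`, with `p_j = 1` and `b` drawn i.i.d. from `N(0, μ²_scale)` and
frozen (defaults m = 100 → 200 dimensions, μ_scale = 10).  Zero-mean
Gaussian frequencies are the standard random-Fourier-features convention;
μ_scale sets the bandwidth of the features and hence how sharply the
generator can distinguish nearby ages.  The map is smooth, so gradients
reach the age through it; the ordinal (thermometer) encoding kept in
`conditioning.ordinal_encode` exists to demonstrate the alternative's
failure: a gradient step applied to `[1,1,1,0,0]` yields values outside
{0, 1} and broken monotonicity, and projecting back is not differentiable.
Both factors share a single encoding vector rather than one embedding per
factor, which scales to many conditions without extra embedding networks.

## The synthetic world

The simulator renders a stylised 2D brain slice in normalised [-1, 1]²
coordinates (default 64×64; resolution is a pure sampling knob) with
intensities in [-1, +1]:

* an elliptic **tissue shell** (semi-axes ≈ 0.80/0.88, per-subject jitter
  ±5%) that shrinks by 14% per unit of *age* across the 60–90 range —
  global shrinkage is a diagnosis-independent ageing signature;
* two **lateral-ventricle lobes** whose semi-axes grow linearly with the
  effective atrophy `t = (age−60)/30 + β_AD·diagnosis`, β_AD = 0.3, so an
  AD brain's interior resembles a control roughly nine years older — the
  disease/ageing confusability the method exploits;
* two **temporal-horn spots** (radius 0.025 for CN, +0.05 for AD) at a
  per-subject mirrored position — the genuine disease cue, deliberately
  position-variant so it is harder to learn than the global shell size;
* a smooth per-subject **texture field** (amplitude 0.10) and optional
  Gaussian pixel noise (σ = 0.02) frozen per sample at dataset creation, so
  datasets are fixed artifacts and selection/metrics are reproducible.

All region edges are logistic in the squared elliptic radius (temperature
τ = 0.02), and every age-dependent quantity is linear in age, so
`∂image/∂age` exists in closed form; the noise never enters the gradient
path.  `render_with_age_grad` returns it, and the `OracleGenerator` — which
re-renders the same subject at the requested target age, noiselessly — is
therefore an exactly differentiable counterfactual generator covering both
ageing and rejuvenation with one mechanism.  Diagnosis is never altered by
the oracle, enforcing label preservation at the simulator level.

The salience balance between the shell (easy, global, age-only) and the
horns (hard, local, disease-only) was calibrated once so that the two
study-defining properties hold simultaneously: a classifier trained on an
uncoupled cohort must exceed 90% test accuracy (it can find the horns), and
a classifier trained on the age-coupled cohort must collapse on the test
cells where the coupling breaks (it prefers the shell shortcut).  With
horn-gain 0.05 and shell-shrink 0.14 the uncoupled test accuracy is
0.96–1.00 and the coupled worst group 0.26–0.53 across seeds.

What the world does **not** emulate: anatomy, MRI contrast and artefacts,
3D structure, registration error, longitudinal intra-subject noise, and any
overlap structure between disease and ageing beyond a single scalar atrophy
axis.  Passing tests therefore show that the *mechanism* — selection,
differentiable conditioning, ascent toward missing regions of the condition
space, replay — behaves as designed, not that it transfers to clinical
data.

## Models

Both networks are NumPy implementations with hand-derived backpropagation,
which keeps the input-gradient and age-gradient paths explicit and exactly
testable against finite differences.

* **Classifier**: one tanh hidden layer (48 units) over flattened pixels,
  plus a linear pixel→logit skip path, sigmoid output, trained with Adam on
  binary cross-entropy (pre-training default: 3e-4 learning rate, batch 32;
  1e-4 during adversarial updates).  The skip path keeps gradients alive if
  the hidden layer saturates — without it, training on some cohorts
  collapses onto the p = 0.5 plateau.  A single-logit sigmoid is used
  rather than a two-class softmax; the two are equivalent for binary
  labels.
* **Neural generator**: `concat(flatten(x), γ(v)) → tanh(256) → tanh` per
  pixel, trained by regressing onto oracle counterfactuals at random target
  ages (4 random pairs per training sample plus the identity pair, mean
  squared pixel error, Adam 1e-3).  Held-out counterfactual error is
  ≈ 0.03 intensity units.  A supervised regression stands in for the
  original adversarial training of such generators because the method
  consumes only the contract — differentiable in `a`, realistic outputs —
  and treats `G` as pre-trained and frozen.  Training aborts with a
  diagnostic if the loss stops decreasing over a 10-epoch patience window.

## Numerical and design choices

* **Ascent step γ_a = 50 on the year scale**, one ascent step per outer
  iteration.  The gradient is taken through the normalisation, so its
  natural size is (loss change)/(year); a desk-scale classifier fits its
  training split closely, leaving per-sample gradients of order 0.01/year,
  and the step must move ages by whole years within k = 5 iterations to
  reach the under-represented regions.  Clipping to [60, 90] after every
  update bounds any overshoot.  The step size is configurable and should be
  re-tuned if the classifier is substantially less converged.
* **Hard-sample "error" is the continuous BCE loss**, not 0/1
  misclassification, so exactly N samples can always be ranked out.
* **Selection happens once**, before the loop; a `reselect_hard` flag
  exists but is off by default.
* **Full-batch age gradients** over the hard set (N ≤ 100 keeps this
  cheap); no mini-batching of the age update.
* **Seeding**: one master seed fans out via `SeedSequence` into named
  sub-seeds (selection, initialisation, data order, buffer draw), all
  logged in the run history; every component is deterministic given its
  seed.
* **Degenerate cases**: requesting more hard samples than the split holds
  is an error in the main loop but a clamp-with-warning in the continual
  loop, whose buffer can legitimately be tiny at small M; ventricles that
  would outgrow the shell are clamped with a logged warning.
* **Evaluation**: half-open age bins ([60,70), [70,80), [80,90] by default;
  [60,75), [75,90] for the confound study) with the last bin closed, a
  fixed 0.5 decision threshold, AD as the positive class, and worst-group =
  minimum cell accuracy over non-empty (diagnosis × bin) cells.  Overall
  accuracy equals the count-weighted mean of cell accuracies by
  construction.
* **Problem sizes**: studies run at 300–400 subjects, one slice each, with
  32 px images for the method-comparison/continual/generator studies and
  64 px for the confound study; pre-training uses 12 epochs on uncoupled
  cohorts (leaving measurable headroom for the augmentation methods) and 40
  epochs on the coupled cohort (the shortcut is learned to convergence).
  The continual comparison updates at 1e-3 so that retraining on the
  synthetic set alone can actually drift — at vanishing update rates
  nothing forgets and the comparison is vacuous.

## Known limitations

* The toy world's accuracy ceiling is high (≈ 1.0), so method differences
  on the uncoupled cohort are small and orderings between the strong
  methods are soft; the confound study is where the mechanism separates
  cleanly.
* The G-vs-C cautionary mode measures fidelity against the oracle, which is
  only available because the generator was trained on a simulator; with a
  real pre-trained generator the analogous measurement needs held-out
  follow-up images.
* The NIfTI ingestion path is provided for completeness and is untested
  against real cohort data; the oracle generator does not apply to ingested
  images (their subjects carry placeholder anatomy parameters).
* Only the age factor is ascended; the diagnosis channel of the encoding is
  held fixed throughout.
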