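# Methods

## Data model

A record is a pair of `d×n` matrices: values (zero placeholder at missing
cells) and a binary mask, with a strictly increasing timestamp vector in an
arbitrary but consistent unit (no calendar parsing).  The per-feature
time-interval matrix `δ[j,i]` — the elapsed time since feature `j` was last
observed, accumulated across consecutive missing steps and zero at the
first step — is computed and exported.  The decay recurrence itself is
driven by the stage-1 uncertainty score, not by δ: wiring the interval
matrix into the decay heads was considered and left out to keep the
recurrence and its hand-written backward pass minimal, so δ serves
analysis and custom front-ends.

Normalization is per-feature min-max onto `[−1, 1]`, fitted on the union of
observed values across all records (features are shared across records);
constant features map to the midpoint.  The `[−1, 1]` target matches the
tanh generator head.  All error metrics are computed after inverting the
map, on the original measurement scale; observed cells of the final output
are restored from the raw input, so pass-through is exact rather than
merely round-trip accurate.

## Stage 1: adversarial fill

Generator and discriminator are two-hidden-layer fully connected networks
(hidden width = `d` by default, configurable) with tanh hidden units; the
generator output head is tanh (bounded in `[−1, 1]`), the discriminator
head a per-dimension logistic probability.  The generator sees
`[x_t, m_t, (1−m_t)⊙z_t]`; noise `z` is uniform on `[−0.01, 0.01]`
(configurable) — a small perturbation of the zero placeholders, the
distribution being a free choice of this implementation.

The discriminator is trained with masked binary cross-entropy to recover
the mask from the merged vector; the generator with the non-saturating
adversarial term on missing cells plus `α`-weighted squared reconstruction
on observed cells (`α = 10` by default; larger values anchor the fill
harder to the observed marginals).  Probabilities are clamped to
`[1e−8, 1−1e−8]` inside logarithms.  No hint mechanism is used.  Training
is alternating single D/G Adam steps on minibatches of 128 pooled timestep
vectors, learning rate 0.001, for `n_iter` iterations (default 1000).

The per-timestep uncertainty score divides by `k`, the number of observed
dimensions, guarded to at least 1 so fully missing timesteps are defined.
In deployment the residual at a missing cell is taken against the zero
placeholder (there is no other reference); a known ground truth can be
passed explicitly when the score is studied on benchmark data.

## Stage 2: decay correction

Two independent decay heads of the same exponential-relu form map the
scalar uncertainty to a length-`d` input decay and a length-`H` hidden
decay (`H = 16` by default; enough capacity for 5–10-feature benchmarks
while keeping the parameter count in the low thousands).  The hidden state
starts at zero with no decay before any history.

The blend `c_t = v_t⊙fill + (1−v_t)⊙x_t^r` consumes the stage-1 **raw
estimate** for every cell, not the observed-merged fill.  The merged fill
equals the truth at observed cells by construction, so blending it would
give the observed-cell training loss a degenerate optimum — trust the fill
completely (`v → 1`), learn nothing; this failure mode was observed
directly (training loss reaching exactly zero with an identity corrector).
With raw estimates both the fill and the history regression are fallible
predictors wherever the loss is evaluated, and the learned reliability
trade-off transfers to the missing cells.  The final completion step
restores observed cells exactly either way.

The recurrence input is the completed vector concatenated with the mask
(length `2d`).  The default cell is gated (update and reset gates, logistic
gates, tanh candidate) with the decayed hidden state standing in for the
previous state; `literal_eq12=True` selects the plain single-squash
recurrence `h_t = tanh(W_h ĥ_{t−1} + P_h[x^c∘m] + b_h)` instead.  The gated
default reflects the standard decay-cell design; the literal mode keeps the
printed single-equation recurrence available and testable.

Numerical choices that matter:

- relu subgradient at exactly 0 is taken as 1 in the decay-head backward
  pass, so a head sitting at the hinge (zero uncertainty, zero bias)
  remains trainable;
- decay biases are initialized at 0.1 (so `v ≈ 0.9` at zero uncertainty):
  the blend starts strictly inside `(0, 1)` and both paths receive gradient
  from the first step;
- decay slopes are initialized positive (|N(0, 0.1)|), encoding the prior
  that higher uncertainty should decay trust in the fill;
- training is full-length backpropagation through time (no truncation);
  records are grouped by length and each group processed as one dense
  batch; records shorter than 2 steps are skipped with a warning;
- the loss is the observed-cell mean absolute error of the blended
  estimate, normalized by the observed-cell count.

All analytic gradients (both stages, both recurrence modes) are verified
against central finite differences in the test suite.

## Baselines

Zero, per-feature mean, last observation carried forward (leading missing
runs fall back to the feature mean), and KNN across timesteps: masked
Euclidean distance over co-observed features normalized by the co-observed
count, `k = 5` nearest observing timesteps, inverse-distance weights (zero
distances dominate); cells with no candidate fall back to the feature
mean.  `k` and the distance are free choices documented here, as the
classical method is cited without parameters in this literature.

## Metrics

RMSE and MAPE are restricted to the artificially hidden cells, original
scale.  MAPE is undefined at zero truths and raises, instructing the caller
to exclude such cells; the benchmark generator keeps truths bounded away
from zero so the metric is always defined there.  AUC uses the standard
pairwise (Mann–Whitney) normalization `|D+|·|D−|` with ties counted 0.5 —
a sum normalized by `|D+|+|D−|` cannot reach 1 for perfect separation, so
the pairwise form is taken as the intended reading; ties at 0.5 are a
documented choice.

## Synthetic benchmark

Each record draws a latent AR(1) process per feature (`φ = 0.8` by
default — strong temporal autocorrelation, the regime where a temporal
corrector can demonstrate value), mixes features linearly (mixing 0.3),
adds per-feature offsets `10 + 2j` (values bounded away from zero with a
floor at 0.5 so MAPE is defined), and jitters timestamps (`1 ± 0.3` per
step, strictly increasing).  Default scale: 5 features × 100 steps × 50
records, MCAR rate 0.3, seed 1024.

Corruption is cell-level MCAR at a configurable rate, plus the record-level
"secondary missing" protocol: record indices drawn as
`round(N(R/2, R/6))`, clipped to range; a complete record is deleted whole
(and logged as held out with its ground truth), an already-incomplete one
advances the scan to the next index; deletion stops at the target overall
missing rate or, with a warning, when no complete record remains.

What the generator does *not* emulate: heavy-tailed and bounded
physiological marginals, measurement error structure, informative
missingness (MNAR), feature-specific sampling schedules, and cross-record
heterogeneity of scale.  Passing results on this benchmark demonstrate the
mechanics and the relative ordering of methods under controlled temporal
structure, not clinical-grade accuracy on real EHR extracts.

## Problem sizes

Unit tests run on toy instances (2–4 features, 10–60 steps).  The
benchmark-scale checks and the acceptance script use the default fixture
(5×100×50) with training reduced to 100 adversarial iterations and 100
corrector epochs — orders of magnitude below the 1000-epoch defaults, a
size chosen so the full ablation (4 variants × 10 seeds) and the
missing-rate sweep (4 rates × 5 seeds) each complete in about a minute on
one CPU while preserving the qualitative orderings they test.

## Known limitations

- The adversarial stage pools timesteps as i.i.d. vectors; temporal
  structure enters only through stage 2.
- With heavily reduced training the adversarial fill is weaker than the
  mean baseline on the benchmark; the corrector recovers much of the gap,
  and longer training (the 1000-iteration defaults) closes it further.
- Sequential training only (stage 1 to convergence, then stage 2); no
  joint fine-tuning.
- Single device, CPU; no truncated backpropagation, so very long records
  (thousands of steps) will be slow and memory-hungry.
- The uncertainty score is a scalar per timestep; per-feature uncertainty
  is not modelled.
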