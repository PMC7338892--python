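# Methods

This note documents the models, the synthetic data, the numerical
choices and the open design decisions behind `neurocca`.

## Models and assumptions

All models are linear, deterministic and rate-based: a neuron's output
is a weighted sum of its inputs, updated once per presented sample.
Plasticity is stochastic gradient ascent on the weights and descent on
Lagrange multipliers of a constrained correlation objective, with one
sample per step (no minibatching, no momentum).  Solutions are defined
up to sign — `(a, b)` and `(−a, −b)` are equally optimal — and the
trainers do not control the sign; the metrics resolve it (per-component
joint alignment for multichannel, one global flip for multiview).

**Single channel.**  The Lagrangian of the unit-variance-constrained
correlation objective, after completing the square, is
`(1/2T) Σ_t (aᵀx_t + bᵀy_t)² − (α/2)(var_a − 1) − (β/2)(var_b − 1)`.
Its saddle points put `(a, b)` at a canonical pair; at the top pair the
multipliers satisfy `α = β = 1 + ρ₁`, which the tests use as a
recovery check.

**Multi-channel (deflation network).**  Component `d` is found assuming
components `1..d−1` are known, with the decorrelation constraint
expressed in *summed outputs* `c_i = a_iᵀx + b_iᵀy` rather than in
per-view currents.  This yields a strictly lower-triangular lateral
matrix `M` and the local anti-Hebbian rule `ΔM[i,j] ∝ c_i c_j` (the
somatic output is the only signal a neuron exposes).  The rule obtained
directly from the gradient, `ΔM[i,j] ∝ (c_a,i + c_b,i) c_j`, is kept
behind `local_rule=False` so the two can be compared.  The strictly
triangular forward pass needs no settling dynamics.  At the desired
fixed point the outputs are uncorrelated and `M = 0`; other fixed
points exist in principle, and convergence to the desired one is
verified empirically, not analytically.

**Non-local baseline.**  The standard multi-channel Lagrangian carries
`d(d−1)` decorrelation multipliers per view (`Gamma_a`, `Gamma_b`,
symmetric, zero diagonal) whose updates need the distal/proximal
currents of *other* neurons.  We reconstruct its online algorithm by
the same gradient recipe as the single-channel rule.  Because the
multiplier parameterization of such a baseline is not unique, only its
qualitative behavior (failure to converge under online training) is
asserted, never its trajectory.

**Multiview (SUMCOR).**  The sum-of-pairwise-correlations objective
with per-view unit-variance constraints; one `k`-compartment neuron,
each compartment running the single-channel rules with the somatic sum
as the shared error signal.  With `k = 2` the model *is* the
single-channel neuron, and the implementation preserves this reduction
bit-for-bit (identical floating-point operation order in the compiled
kernels); likewise a `d = 1` network is bit-identical to the single
neuron.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `base` learning rate (multichannel) | 0.02 | shared base rate for `η_a, η_b, η_α, η_β, η_m` |
| decay (multichannel) | `linear-floor`, slope 5e-6, floor 0.1 | `η(t) = 0.02·max(1 − 5e-6·t, 0.1)`; reaches the floor at t = 180,000 |
| learning rate (multiview) | 0.005, constant | shared `η_a^(i) = η_α^(i)` |
| `n_steps` (single / network) | 400,000 | past the schedule floor; convergence plateaus well before the end |
| `n_steps` (multiview) | 10,000,000 | the svd-max inputs have per-sample scale ~T^(-1/2), so the homeostatic variables need ~5×10⁶ steps at the constant rate to pull the weights up to the unit-variance scale; the default sits past that plateau |
| weight init | i.i.d. standard Gaussian (× `init_scale`) | all trainers |
| `α, β` init | 0 | not fixed by the derivation; 0 is symmetric and lets the variance constraint drive them (configurable) |
| oracle ridge | `1e-10·trace(C)/dim` | numerical whitening guard; pass 0 to demand exact invertibility |
| divergence guard | abort at any \|weight\| > 1e6 or non-finite | the quadratic saddle dynamics can diverge for large rates |

Rates are per-parameter configurable but default to a shared base, the
configuration used in all experiments.

## Synthetic data

* **gaussian** — `T = 10,000` joint samples of a 10-dimensional
  zero-mean Gaussian with covariance `GᵀG/100` (`G` standard normal),
  split 5/5 into the two views, centered.  The first `n_x` coordinates
  become `X`: the split is deterministic and documented rather than
  specified by the construction.
* **planted** — shared latent factors give exactly known population
  canonical correlations (default 0.9, 0.2) behind random
  well-conditioned mixing; views are rescaled to the same mean column
  variance (0.1) as the gaussian benchmark so the same learning rates
  are stable.  Used for parameter-recovery tests.
* **svd-max** — per-view SVD factors `U S Vᵀ` sharing the first
  right-singular direction; all other right-singular columns are
  mutually orthonormal across views (sliced from one QR factor).
  Singular values are Uniform([0.1, 1]) sorted descending.  The
  optimum of the multiview objective is `u₁^(i)/s₁^(i)` with maximal
  pairwise correlation exactly 1.  Stored samples-as-rows (the
  transpose of the construction).  SVD sign ambiguity is fixed by
  making the first nonzero entry of each `U` column positive, so the
  ground truth is reproducible.  The dataset is *not* centered: the
  construction's optimum is exact in raw second moments, which is what
  every multiview metric uses.
* **correlated images** — Gaussian random field over the pixel grid
  with squared-exponential covariance `exp(−‖p−q‖²/(2·ℓ²))`; a
  synthetic stand-in for natural-image stacks in which nearby pixels
  are more correlated than distant ones.  Row and quadrant splitters
  (0-based, half-open ranges) turn stacks into paired or 4-view
  datasets.

What the generators do **not** emulate: heavy-tailed or nonnegative
pixel statistics, object structure, nonstationarity, label structure —
passing tests on these generators show that the algorithms recover
known optima under the stated Gaussian/low-rank conditions, not that
they are robust to real-data pathologies.

Training samples are drawn uniformly *with replacement* from the
pregenerated rows (epoch-ordered sampling is available but not
default).  Every generator and trainer is bit-reproducible from its
seed; the seed drives weight initialization first, then the full
sample-index stream.

## Reference solvers

The two-view oracle whitens each covariance (`1/T` normalization
throughout — every printed objective uses it, so `1/(T−1)` is never
used), takes the SVD of the whitened cross-covariance, maps back, and
rescales to exact unit projection variance.  Signs: first nonzero
entry of each `a`-column positive, `b` flipped jointly so `ρ_i ≥ 0`.
Equal canonical correlations make the solution non-unique; ordering
then follows the SVD output and tests avoid constructing ties.

The multiview reference is analytic for svd-max, rescaled by `√T`
because the raw optimum `u₁/s₁` gives projection variance `1/T`: the
rescaling leaves all scale-invariant metrics unchanged while making
the reference satisfy the printed unit-variance constraint.  For other
datasets a full-batch (offline) version of the multiview algorithm —
deterministic ascent/descent on exact covariances — iterates until the
gradient norm drops below tolerance and raises with the final norm if
it does not.

## Metrics

Normalized objective uses the *pooled* normalization printed above
(components summed before the square roots), not per-component
normalization; the two differ when component variances are unequal,
and the pooled form is implemented exactly as defined.  It can
legitimately exceed 1 while constraints are violated.  Angular errors
are data-covariance-weighted cosines evaluated in `atan2` form, which
is numerically exact at 0; sign alignment happens inside the metric,
and the raw (unaligned) value is available.  Component ordering
follows neuron index against oracle rank directly — no permutation
matching — because the deflation architecture makes neuron order
meaningful.  Trace smoothing is a presentation option only and is
never applied to any asserted value.

## Numerical and design choices

* Inner loops are numba kernels with explicit scalar loops, giving a
  fixed summation order; this is what makes the `d=1` and `k=2`
  reductions bit-exact, and makes multi-hundred-thousand-step runs
  take seconds.  Divergence is checked between metric-recording chunks,
  so the reported failure step is chunk-resolution.
* Sequential deflation trains neuron `i` with predecessors frozen,
  splitting the step budget equally and restarting the learning-rate
  schedule per neuron.  Convergence is declared when the relative
  weight change over a 1000-step window falls below 1e-4 — with
  floored rates the stochastic fluctuation usually stays above this,
  so in practice each neuron uses its full budget; budget exhaustion
  is recorded in the trace and warned about.  On freezing, lateral
  weights are removed if they have decayed below 0.1 (`auto`), since
  decay-to-zero is a fixed-point property rather than something to
  force; `zero` and `keep` variants are available.
* "Final" values of a training run are means over the trailing 5% of
  logged points, a fixed documented constant.
* The experiment runner derives run `r`'s seed as `seed + r` and
  writes a manifest sufficient to reproduce every output byte.

## Problem sizes

The default experiment sizes — `T = 10,000` stored samples, `d = 3`
components, 400,000 online steps for the multichannel runs, 10 million
for multiview, 10 repeats — are the sizes at which all reported
behaviors are comfortably converged on one CPU core in seconds per
run; the acceptance checks in `tests/test_acceptance.py` use exactly
these sizes.

## Known limitations

* Linear, noiseless, non-spiking neurons; no dendritic nonlinearities,
  conduction delays or stochastic release.
* The multichannel network extracts a fixed `d` known in advance.
* The non-local baseline is a reconstruction from the Lagrangian, not
  a reimplementation of any particular published variant.
* Online convergence is an empirical property here; no step-size
  conditions are proven, and the divergence guard exists because the
  saddle dynamics genuinely can blow up (the non-local baseline often
  does).
* Real image/video corpora are out of scope; the correlated-image
  generator is a stand-in with the single property (distance-decaying
  pixel correlation) the qualitative claims rely on.
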