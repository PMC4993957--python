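# Methods

## The model

`fermopt` treats medium design as surrogate-assisted optimization: an
expensive experiment (one submerged fermentation of *Phellinus
igniarius*, yielding one total-flavonoid measurement in μg/mL) is
replaced inside the optimizer by a cheap predictive model fitted to a
small set of completed experiments.

**Scaling.** Every column — the nine component concentrations and the
TF target — is min–max scaled with the per-column extremes of the
training set: y = (x − x_min)/(x_max − x_min). The formula maps the
training envelope onto [0, 1]; a `feature_range=(-1, 1)` switch composes
it with 2y − 1 for the symmetric variant. Values outside the envelope
deliberately map outside the range — extrapolation is permitted and
visible, never clamped. Constant columns are rejected at scaling time
(`DegenerateColumnError`) rather than silently producing NaNs.
Concentrations are treated as unitless "values as printed": the packaged
reference tables, the search-box bounds and the reference summary
averages are not mutually consistent in unit labels (g/L vs g/mL, and
three columns lie orders of magnitude outside their stated bounds), and
column-wise scaling makes the surrogate invariant to any single column's
unit. The known inconsistencies are recorded in the fixtures'
provenance strings and surfaced by `summarize_results` as discrepancy
notes.

**Surrogate.** A fully connected 9–H–1 network, tanh hidden units,
linear output, H = 11 by default. The linear output is a deliberate
choice: a bounded (sigmoidal) output could never predict above the
training maximum (1610 μg/mL), which would make "find conditions better
than anything tried" structurally impossible. The price is that
extrapolated predictions are unbounded; the pipeline therefore reports
envelope-excess diagnostics with every optimum (see "Extrapolation"
below).

**Training.** Default trainer is Levenberg–Marquardt on the residual
vector r(θ): each epoch solves (JᵀJ + λI)δ = −Jᵀr with the analytic
prediction Jacobian J, accepts the step only if the training MSE
decreases (λ ← λ/10), otherwise retries with λ ← 10λ. λ starts at 1e-3
and the epoch fails when λ exceeds 1e12, which terminates training at a
local minimum; singular normal equations are handled by the same
escalation, never by crashing. Accepted-step MSE is non-increasing by
construction, and the analytic Jacobian/gradient is property-tested
against central finite differences (≤1e-5 relative). Møller's scaled
conjugate gradient (standard constants: σ = 1e-4, initial λ = 1e-6) is
provided as the alternative trainer; the two run independently and are
never chained. Stopping: MSE ≤ `target_mse` (default 0.019 scaled
units — the level at which the reference surrogate for this problem was
reported trained) or `max_epochs` (default 1000). Initialization is
seeded uniform ±1/√fan_in with zero biases.

With 25 samples and 122 parameters the 9–11–1 network is heavily
over-parameterized. This is intentional and matches its role: the
surrogate is an interpolant of the training runs used as a GA objective,
and the `target_mse` stopping rule is the only regularizer. There is no
weight decay, early stopping on a validation set, or minibatching.

**Hidden-width selection.** Choosing the width that minimizes the
discrepancy between predicted and measured yields is operationalized as 5-fold
cross-validated MSE averaged over 3 random restarts per fold, minimized
over candidate widths 3–13, ties toward the smaller network. With 25
noisy samples the selection is intrinsically unstable; the default
width is simply fixed at 11, with selection available via
`hidden_size_mode="selected"`.

## The genetic algorithm

Real-coded chromosomes (one concentration per gene, canonical component
order), generational loop with:

- **Roulette selection**: P(xᵢ) = f(xᵢ)/Σⱼ f(xⱼ). Fitness vectors
  containing negatives (the surrogate's linear output can go negative)
  are shifted by the generation minimum plus a 1e-12 floor before the
  wheel; an all-zero vector falls back to uniform with a warning.
- **Whole-arithmetic crossover** (probability 0.8, valid range 0.6–1):
  one λ ~ U(0,1) per mating, children λa+(1−λ)b and (1−λ)a+λb. Convex
  combinations keep offspring inside the box by construction.
- **Uniform-reset mutation** (per-gene probability 0.05, valid range
  0.01–0.1): a mutated gene is resampled uniformly within its own
  bounds.
- **Elitism 1**: the best individual is copied unchanged, which makes
  per-generation best fitness non-decreasing (property-tested).

Defaults: population 300, 200 generations (100/150/200/500 are the
conventional presets for this problem), seed-driven throughout. The
default box, in g/L: glucose 0–40, maltose 0–40, mannitol 0–40, corn
powder 0–100, yeast 0–100, copper sulfate 0–0.5, sodium chloride 0–10,
ferrous sulfate 0–0.5, vitamin B₁ 0–0.1. Crossover 0.8 and mutation
0.05 are the midpoints of the stated valid ranges.

A behavioral note that matters for benchmarking: with uniform-reset
mutation, a gene that contributes negligibly to fitness (e.g. vitamin
B₁, box width 0.1, inside a raw-unit quadratic dominated by the
width-100 genes) never converges below a stationary noise floor of
roughly 9% of its box width, at any evaluation budget — mutation keeps
reinjecting uniform draws and selection cannot see the difference. The
test suite therefore checks tight (≤5% of width) optimum recovery on a
width-normalized concave benchmark where every gene carries equal
selection pressure, and separately checks that the GA dominates a
random-search baseline of equal budget on the unnormalized one.

## The hybrid pipeline and extrapolation

One hybrid run = fit scaler → train surrogate → GA-maximize the
surrogate's scaled prediction → inverse-scale the best fitness to
μg/mL. The ensemble repeats this over `n_runs` independent seed pairs
(default 10; 100 mirrors the full-scale workflow) derived from one base
seed via `SeedSequence`, retraining the surrogate per run by default
(`retrain_per_run=False` shares one surrogate and varies only the GA).
A run whose training diverges is dropped; all-failed raises. The
headline statistic is the ensemble **median** predicted yield — the
mean is unstable under extrapolation outliers; both are reported.

The default search box and the training data disagree severely: the
training values for copper sulfate (5–6.25), ferrous sulfate (10–25)
and vitamin B₁ (1.5–1.875) lie entirely *outside* their box bounds
(0–0.5, 0–0.5, 0–0.1). In scaled units every chromosome in the box has
those three inputs at −4 to −0.6, so every box optimum is a deep
extrapolation of the surrogate, and the ensemble median predicted
yield is governed by the tanh/linear network's behavior far from its
data — it typically lands well above both the training maximum and the
previously reported ≈2200 μg/mL optimum, with large run-to-run spread.
The package does not hide this: predictions are never clamped, each
result carries its per-component envelope excess, and all outputs label
yields as *surrogate-predicted*. An `envelope_bounds` helper widens the
box to cover the training data for users who prefer to search inside
the evidence. No wet-lab validation of any predicted optimum exists.

## The synthetic generator

`SyntheticSpec` emulates the data-generating process the wet lab would
provide: chromosomes uniform over the box, yields from a known concave
surface plus i.i.d. Gaussian noise. The default surface is a negative
quadratic, y(x) = peak − Σⱼ cⱼ(xⱼ − optⱼ)², with a unique interior
optimum and curvatures normalized per gene so the total drop at the
farthest box corner equals `depth` — every gene is equally informative
and all yields stay in [peak − depth, peak]. Defaults, chosen once as
realistic for this assay: peak 2000 μg/mL, depth 1500, noise SD
50 μg/mL (≈3% of typical yields), 200 samples. A `multimodal` variant
adds a cosine ripple for stress tests.

What passing the recovery tests shows: on noiseless, smooth, concave
ground truth with ample samples, surrogate + GA finds the true optimum
to ≤10% of box width per gene. What it does not show: robustness to the
features real fermentation data have — few samples, fractional-factorial
design structure rather than uniform coverage, heteroscedastic assay
noise, non-concave response, and box/envelope mismatch. The reference
25-row table has all of these, which is exactly why its ensemble
results must be read as extrapolations.

## Numerical and interface choices

- Scaled-unit MSE everywhere (inputs/outputs are normalized); the
  0.019 default threshold is in those units.
- Fixture CSV cells serialize via shortest-exact decimal strings
  (`%.12g`), so fixture → CSV → fixture round-trips are byte-identical.
- Degenerate GA bound pairs (lower == upper) are legal and pin the gene.
- Trained models serialize to plain JSON (shapes, flat parameter
  arrays, activation names, scaler) and round-trip bit-exactly.
- All randomness flows from explicit integer seeds; derived child seeds
  are 31-bit. A run's (seed, config) pair reproduces its outputs
  byte-for-byte.
- Test problem sizes: the ensemble tests use 10 runs at the default
  GA budget; CV-based width selection defaults to 200 training epochs
  per fold-restart.

## Known limitations

- The surrogate is an interpolant; its extrapolations are unvalidated
  and unbounded, and the default box guarantees extrapolation (above).
- Roulette selection is the only selection operator (no tournament or
  rank selection, no adaptive rates, no islands), matching the plain
  scheme this workflow is built around.
- No unit-conversion engine: columns are values-as-printed, and the
  recorded unit inconsistencies in the reference tables are surfaced,
  not resolved.
- Hidden-width selection on 25 samples is unstable across seeds; treat
  any selected width as "a reasonable width", not an optimum.
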