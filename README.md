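# fermopt

Surrogate-assisted optimization of fermentation media for flavone
production by *Phellinus igniarius*.

*Phellinus* is a medicinal fungus whose submerged fermentation produces
flavones (total flavonoids, **TF**, measured in μg/mL of broth). Yield
depends on the composition of the fermentation medium — here nine
components: glucose, maltose, mannitol, corn powder, yeast extract,
cupric sulfate, sodium chloride, ferrous sulfate and vitamin B₁. Because
each wet-lab fermentation takes days, exhaustive screening of the
9-dimensional composition space is impractical. `fermopt` implements the
classic surrogate-assisted alternative for this problem, aimed at
bioprocess engineers and at anyone studying small-data surrogate
optimization:

1. **Surrogate.** A single-hidden-layer back-propagation neural network
   maps medium composition to predicted TF yield. Inputs and the target
   are min–max scaled per column over the training set,

   y = (x − x_min) / (x_max − x_min),

   and the network is 9–11–1 (tanh hidden units, one *linear* output
   unit), trained by Levenberg–Marquardt (damped Gauss–Newton on the
   residuals; scaled conjugate gradient is also available). The hidden
   width can instead be selected from 3–13 by cross-validation.

2. **Optimizer.** A real-coded genetic algorithm maximizes the trained
   surrogate over a bounded concentration box (population 300, roulette
   selection with P(xᵢ) = f(xᵢ)/Σⱼ f(xⱼ), whole-arithmetic crossover,
   uniform-reset mutation, one elite).

3. **Ensemble.** Because both training and the GA are stochastic, the
   headline workflow repeats train-then-optimize over many seeds and
   reports the median best *surrogate-predicted* yield, with every
   optimum annotated by how far it extrapolates outside the training
   envelope.

The package ships two reference tables: 25 training conditions with
measured yields (maximum 1610 μg/mL) and 10 previously reported
optimized conditions (predicted ≈2200 μg/mL), plus a synthetic
response-surface generator with a known optimum for validating the whole
pipeline.

## Worked example

Train the surrogate on the packaged training table and inspect the fit:

```
$ fermopt train src/fermopt/data/table1.csv --out model.json --seed 0
trained 9-11-1 surrogate on 25 records: MSE=0.017779 (scaled units), epochs=18, converged=True
model written to model.json
```

The MSE is in scaled (unit-interval) response units; 0.0178 corresponds
to a root-mean-square error of about 116 μg/mL on the 740–1610 μg/mL
training range. With 25 samples and over 120 free parameters the network
interpolates the training data rather than generalizing — that is the
intended use: it is an objective function, not a forecasting model.

Run a small hybrid ensemble on the same data:

```
$ fermopt reproduce --out-dir out --n-runs 3 --seed 0
hybrid ensemble on the 25 packaged training conditions (seed=0, n_runs=3)
median surrogate-predicted yield: 5030 ug/mL
mean surrogate-predicted yield:   5920 ug/mL
training-set maximum yield:       1610 ug/mL
runs extrapolating outside training envelope: 3/3
...
```

Every run's optimum lies outside the training envelope, and the
predicted yields far exceed the training maximum: the default search box
forces three components (cupric sulfate, ferrous sulfate, vitamin B₁)
well outside the range the surrogate was trained on, so these numbers
are deep extrapolations and should be read as *candidate conditions to
test in the lab*, never as validated yields. See `docs/methods.md` for
the full discussion.

End-to-end validation against a known ground truth uses the synthetic
generator:

```
$ fermopt synth --out synth.csv --n-samples 200 --noise-sd 0 --seed 0
wrote 200 synthetic records to synth.csv
true optimum: [20.0, 18.0, 22.0, 40.0, 35.0, 0.3, 6.0, 0.2, 0.06] (peak 2000.0)
$ fermopt optimize synth.csv --out-dir synth-out --n-runs 2 --seed 0
```

On this noiseless concave surface the hybrid recovers the true optimum
to within 10% of the box width per component (this is asserted in the
test suite).

All commands accept `--seed`; identical seeds reproduce outputs exactly.
`fermopt --show-config` prints every default as YAML.

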