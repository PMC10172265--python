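# spinecreep

Tools for analyzing the temperature- and loading-history-dependent
viscoelasticity of human lumbar spinal segments (L4L5) under cyclic pure
moment loading, and for training a recurrent surrogate that predicts how the
moment–RoM hysteresis curve evolves cycle by cycle.

## The problem

A spinal segment loaded cyclically to ±7.5 Nm traces a hysteresis loop in
the applied moment *m* (Nm) vs. range of motion *RoM* (degrees) plane.  Under
repeated 30-minute loading blocks the loop's amplitude creeps upward — more
strongly at body temperature (BT, 37 °C) than room temperature (RT) — and
partially recovers during 15-minute breaks.  Each branch of a loop is
parameterized by a modified double Boltzmann sigmoid

    RoM(m) = A / (1 + e^{a₁(m − m₁)}) − B / (1 + e^{a₂(m − m₂)}) + B

with *A* and *B* the minimum and maximum RoM of the curve, so a full cycle is
10 numbers (A, B shared; slopes a₁, a₂ in 1/Nm and centers m₁, m₂ in Nm per
branch).  Fits with pooled R² ≥ 0.985 are accepted.  Creep is summarized by

    r_load  = RoM₃,start / RoM₃₀min      (< 1 ⇒ creep within a block)
    r_break = RoM₃₀min / RoM₃,break      (> 1 ⇒ recovery during a break)

with RoM taken at +7.5 Nm.  The surrogate 𝓕_NN maps the 2nd cycle's 10
parameters plus an environmental feature τ_t (group Kendall τ of r_load vs.
total testing time × the block's start hour) to the parameters of every
following cycle: stacked LSTM layers with a linear dense head, trained with a
sequence-masked mean-squared-error loss and Adam.

The package bundles: the curve model and fit-quality gate
(`spinecreep.hysteresis`), creep/recovery statistics with Kendall-τ, Fisher-z
and rank tests (`spinecreep.creep`), a calibrated synthetic generator that
reproduces the reference experiment's group medians (`spinecreep.synthetic`),
the [−1, 1] feature scaler and the LSTM surrogate as scikit-learn style
estimators (`spinecreep.scaling`, `spinecreep.surrogate`, `spinecreep.nn`),
and an orchestrating pipeline/CLI (`spinecreep.pipeline`, `spinecreep.cli`).
It is written for biomechanics researchers who want to analyze per-cycle
loop-parameter tables or prototype surrogate models without cadaver data.

## Worked example

```python
import numpy as np
from spinecreep import (build_dataset, SurrogateConfig, fit_hysteresis,
                        sample_loop, random_loop_params, sequence_ratios)

# 1. Fit one noisy synthetic loop
rng = np.random.default_rng(0)
params = random_loop_params(rng)
fit = fit_hysteresis(sample_loop(params, 100, noise_sigma=0.05, rng=rng))
print(f"pooled R2 = {fit.r2_total:.4f}, accepted = {fit.accepted}")
# pooled R2 = 0.9998, accepted = True

# 2. Generate the default dataset (180 sequences, both temperature groups)
sequences, split = build_dataset(seed=0)
bt = [s for s in sequences if s.temperature == "BT" and not s.flipped]
print(f"median r_load (BT) = {np.median([sequence_ratios(s)[0] for s in bt]):.4f}")
# median r_load (BT) = 0.9371

# 3. Train the desk-scale surrogate (a few minutes on one CPU) and score it
by_id = {s.sequence_id: s for s in sequences}
model = SurrogateConfig.desk(seed=0).to_estimator()
model.fit([by_id[i] for i in split.train])
print(model.stop_reason_, f"loss = {model.log_.final_loss:.2e}, epoch {model.n_epochs_}")
# target_loss loss = 4.94e-04, epoch 1538
print(f"validation mean R2 = {model.score([by_id[i] for i in split.validation]):.4f}")
# validation mean R2 = 0.9999
```

The fit line shows a loop whose double-Boltzmann description explains 99.9 %
of the RoM variance despite 0.05° measurement noise — comfortably above the
0.985 acceptance gate.  The body-temperature median r_load below 1 quantifies
within-block creep, and the training run stops once the masked MSE reaches
its 5×10⁻⁴ target; the validation mean R² compares predicted and true
reconstructed hysteresis curves cycle by cycle.

A command-line interface mirrors the pipeline:

```bash
spinecreep --seed 0 --out run/ simulate        # dataset CSV + split manifest
spinecreep --seed 0 --out run/ train           # full pipeline incl. training
spinecreep --out run/ stats run/sequences.csv  # creep statistics report
```

## Layout

```
src/spinecreep/     library modules
tests/              pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py
docs/methods.md     model assumptions, calibration and limitations
```
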