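# bitegape

Neural encoding and population decoding of **bite force** and **static gape**
in orofacial sensorimotor cortex (MIo, SIo, CMA), implemented as a tested
analysis pipeline over task-structured synthetic data with known ground
truth.

During incisor biting, a subject holds the jaw at one of three static gapes
while generating one of three bite-force levels (9 trial types). The package
asks, at two scales, how cortical spiking represents those two variables:

* **Single neurons** — a point-process Bernoulli GLM of each neuron's
  spiking in 4-ms bins over ±500 ms around force onset (FO):

  ```
  logit p_n(t) = β₀ + Σⱼ βᴴⱼ Hⱼ(t) + βᴳ G + Σₖ βᶠₖ F(t+τₖ) + Σₖ βᴳᶠₖ (G−Ḡ)·F(t+τₖ)
  ```

  with spike history Hⱼ filtered through raised-cosine bases at 16/44/108 ms
  timescales, static gape G (mm), and bite force F sampled at 8 lags τₖ from
  −156 ms (force leads spiking) to +208 ms (force lags) in 52-ms steps — 17
  extrinsic features. Full and reduced models are fit per neuron under
  shared 10-fold trial-level cross-validation and scored by AUROC; paired
  comparisons ask whether removing force (or gape) degrades prediction.

* **Populations** — demixed PCA decomposes trial-averaged activity into
  X = X_time + X_gape + X_force + X_interaction (+ noise), finding encoder/
  decoder pairs per marginalization by minimizing
  L = Σ_φ ‖X_φ − F_φ D_φ X‖². The first decoding axis of each marginalization
  then serves as a fixed linear classifier of single trials per 50-ms bin,
  with chance estimated by label shuffling: a bin is significant when the
  actual accuracy exceeds all shuffled accuracies (nominal p = 1/500 = 0.002
  at the default 500 shuffles).

The synthetic-data module generates the full task — balanced 3×3 trials,
bite-force ramps with overshoot and tremor, FO detected by sustained
threshold crossing — plus spike trains from known GLM coefficients and
latent populations with known variance fractions per marginalization, so
every stage is testable by parameter recovery.

## Layout

```
src/bitegape/      core (data model, binning, PETH, I/O), synth, glm, dpca,
                   decode, cohort
analysis/          numbered drivers: 01 simulate … 05 cohort report
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py (recomputes headline quantities)
```

## Worked example

```
$ python analysis/01_simulate_session.py
task: 135 trials, gapes (11.0, 14.0, 17.0) mm, force targets (1.0, 2.0, 3.0) V
GLM cohort: 18 neurons, 36872 spikes (~15.2 Hz in-window), 0 probability clamps
latent population realized variance fractions: {'time': 0.499, 'gape': 0.195,
 'force': 0.202, 'interaction': 0.104}

$ python analysis/02_encoding_models.py
median mean-AUROC by model:
gape_only      0.497
force_gape     0.568
...
full           0.625
force removed from joint model: median AUROC drop 0.077, signed-rank p = 3.8e-06
gape removed: signed-rank p = 1 (gape truth is null in this cohort)
force-related 18/18, gape-related 1/18
history |beta| medians: {'16ms': 1.25, '44ms': 0.4, '108ms': 0.1}
```

The cohort was simulated with force tuning and no gape tuning: the gape-only
model sits at chance (0.497), removing force from the joint model costs
0.077 AUROC (signed-rank p ≈ 4e-6) while removing gape costs nothing, every
neuron is flagged force-related, and the shortest spike-history timescale
carries the largest coefficients — the fitted models recover exactly the
structure that was put in. `03_population_dpca.py` recovers the latent
population's variance fractions (e.g. time 45.2% fitted vs 49.9% ground
truth), and `04_decoding.py` traces per-bin classification accuracy against
its shuffle null.

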