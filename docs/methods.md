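# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `bitegape`, in the spirit of a package's model
documentation: what is computed, under which assumptions, and what the tests
do and do not establish.

## Task and data model

The behavioral unit is an incisor-biting trial: the jaw is held at one of
three static gapes (defaults 11/14/17 mm) while the subject produces one of
three bite-force levels, giving 9 trial types. All neural analyses align to
**force onset (FO)** — the time the force trace first rises toward target —
and operate on spike counts in 4-ms bins over ±500 ms around FO (250 bins).

Numerical conventions:

* Bins are half-open `[left, right)`, left-aligned to −500 ms; a spike
  exactly at +500 ms is excluded. Binning is `floor((t − fo − w₀)/Δ)` on
  spike times stored as seconds, which makes the tensor reproducible across
  platforms and translation-equivariant (shifting all spikes and FO by the
  same Δ leaves it unchanged — tested).
* PETHs smooth each trial's rate with a truncated Gaussian (±3σ, σ = 50 ms
  by default) renormalized at the window edges, so a constant rate maps to
  itself everywhere; mean and ±1 SEM are taken **across trials** after
  smoothing.
* Unsuccessful trials are excluded from binning by default
  (`include_failed=True` retains them).
* Datasets are plain CSV (spike events; trial table) plus an HDF5 container
  for force traces; round-trips are lossless to stored precision.

## Single-neuron encoding model

Per-bin spiking is Bernoulli with a logit link:

logit p(t) = β₀ + Σⱼ βᴴⱼ Hⱼ(t) + βᴳ G + Σₖ βᶠₖ F(t+τₖ) + Σₖ βᴳᶠₖ (G−Ḡ)·F(t+τₖ)

* **Spike history.** Hⱼ filters the neuron's own binarized spike train
  through raised-cosine bases with timescales 16/44/108 ms:
  bⱼ(τ) = ½(1 + cos(π(τ−cⱼ)/wⱼ)) with cⱼ = wⱼ = timescaleⱼ/2, sampled on the
  4-ms lag grid starting at one bin (no instantaneous self-coupling), zero
  outside its support. History never crosses trial boundaries; leading bins
  see zero-padded history.
* **Force lags.** F is read from the trial's force trace at bin-center time
  plus τₖ, for the 8 lags −156 … +208 ms in 52-ms steps; negative lags mean
  force *leads* spiking, positive lags mean force follows it.
* **Interaction.** The product covariate uses *centered* gape, (G−Ḡ)·F.
  With gape values far from zero an uncentered product is ≈ 0.99-correlated
  with F itself, and separating βᶠ from βᴳᶠ amounts to extrapolating gape to
  0 mm — the force coefficients become unidentifiable (their standard errors
  exceeded the coefficients several-fold in design analysis). Centering the
  moderator is the standard remedy; it changes only the parameterization,
  not the fitted model class, and the generator uses the identical
  definition so recovery is exact. Counting gape, the 8 force lags, and the
  8 interactions, the model has 17 extrinsic features plus 3 history terms
  and an intercept.

**Fitting.** Maximum likelihood by IRLS with a tiny ridge (10⁻⁶) for
conditioning; "converged" means the penalized score's infinity norm fell
below 10⁻⁶ within 100 iterations (complete separation fails this and is
flagged rather than erroring). Standard errors come from the inverse
penalized Fisher information. Cross-validation splits at the **trial**
level into 10 folds, stratified over the 9 trial types so every fold
contains every condition; the same partition is reused by every model spec
for a neuron, making paired AUROC comparisons exact. Responses are counts
clipped to {0, 1} (a 4-ms bin essentially never holds two spikes; the
clipped fraction is recorded).

**Model zoo.** `full` = history + gape + force + interaction; removals drop
the named group *and* any interaction whose parent was removed (`no_gape` =
history + force, `no_force` = history + gape, `no_force_no_gape` = history);
`force_only`/`gape_only`/`interaction_only`/`history_only` are literal
single-group models plus intercept. `force_gape` (gape + force, no
intrinsic terms) is the joint model used for the force-removed vs.
gape-removed scatter comparison. Test-fold AUROC uses the Mann–Whitney
formulation (ties count half); chance defaults to 0.5, with
`empirical_chance_auroc` providing a trial-shuffled alternative — note that
because every trial shares the post-onset temporal profile, the empirical
chance level can sit above 0.5, which is precisely the bias the shuffled
mode exposes.

**Derived analyses.**

* *Classification*: a neuron is force- (gape-) related when its force-only
  (gape-only) model converged in ≥ 6 of 10 folds and a one-sided Wilcoxon
  signed-rank test of the fold AUROCs against 0.5 gives p < 0.05.
* *Preferred force lag*: among force-only coefficients whose Wald z (β/SE,
  normal reference) gives two-sided p < 0.05, the lag with the largest |β|;
  exact ties break toward the most negative (leading) lag; neurons with no
  significant lag are excluded and counted.
* *History timescales*: Kruskal–Wallis across the three |βᴴ| samples with
  Bonferroni-corrected pairwise rank-sum follow-ups, per area or pooled.
* *Single-lag control*: per neuron, six logistic models of the spike
  indicator in one 4-ms bin (60–160 ms post-FO in 20-ms steps) on gape,
  force at +100 ms, and their product, each compared with its force- and
  gape-removed reductions.

## Population decomposition (dPCA)

Trial-averaged smoothed rates form a tensor X[neuron, gape, force, time].
After removing each neuron's grand mean, the centered tensor splits exactly
into four orthogonal marginalizations — time (condition mean), gape (gape
main effect + gape×time), force, and interaction (gape×force and
gape×force×time). For each marginalization φ the encoder/decoder pair
minimizes ‖X_φ − F_φ D_φ X‖² + λ‖F_φ D_φ‖², solved in closed form:
A_φ = X_φ Xᵀ (X Xᵀ + λI)⁻¹ followed by rank truncation via the SVD of
A_φ X (encoders are the top left singular vectors, decoders their
pullback through A_φ). λ is expressed relative to ‖X‖²_F/N; λ = 0 requests
the unregularized solution and is rejected when X Xᵀ is singular. A
split-half cross-validation helper (`choose_regularization`) selects λ from
a log grid by generalization error; per-marginalization noise normalization
is deliberately not applied.

Variance accounting: the "pie" is ‖X_φ‖²/Σ‖X_φ‖² (marginalized variance
fractions of the centered tensor); per-component bars split ‖f dᵀX_φ‖²
across φ; cumulative dPCA variance is compared against the matched PCA
curve, which dominates it at every rank by construction. In the
single-marginalization, λ = 0 limit the procedure reduces exactly to PCA
(tested to 10⁻⁸), and the achieved loss is verified against an independent
full-rank least-squares solution.

Condition cells with fewer than 2 trials are rejected; unbalanced cells are
averaged as-is, and the per-trial tensor used for decoding is balanced by
truncating every cell to the minimum per-cell count in trial-id order
(deterministic).

## Time-resolved decoding

The first decoding axis of the target marginalization (gape: 3 classes,
force: 3, interaction: 9) is a fixed 1-D linear classifier. Each
Monte-Carlo iteration holds out one trial per neuron per condition
(stratified leave-group-out; held-out trials form pseudo-trials — neurons'
trials are combined by condition identity only), refits dPCA on the
training average, projects training class means and test pseudo-trials onto
the axis per 50-ms bin, and assigns each test pseudo-trial to the nearest
class centroid (ties toward the lower class index). Accuracy is the mean
over iterations per bin.

Chance is estimated by repeating the procedure with condition labels
permuted across whole trials within each neuron (preserving per-condition
counts). A bin is **significant when the actual mean accuracy exceeds all
shuffled accuracies**; with the default 500 shuffles this is a nominal
p = 1/500 = 0.002 per bin. Defaults follow the full procedure (1000 CV
iterations, 500 shuffles, axes refit within every iteration); the
`n_cv_per_shuffle` parameter lets each shuffled curve be estimated from
fewer CV repetitions — shuffled curves then scatter more widely than the
actual curve, making the exceed-all rule *conservative* under the null,
which is the direction one wants when trading compute for calibration.

## Synthetic-data generator

The generator is the ground-truth side of every test; it emulates the study
conditions rather than any particular recording.

* **Trials.** Balanced 3×3 design; randomized order interleaves conditions,
  blocked order groups trials by gape with force levels shuffled within a
  block. Force traces (1 kHz) follow a logistic ramp to a target
  proportional to force level (1–3 V), with (i) per-trial ramp-steepness
  variability (lognormal, σ = 0.3), (ii) an overshoot past target that rings
  down during the hold (5–35% of target, 3.5–6 Hz, 0.2-s decay — the task
  permits exceeding the required level before the hold), (iii) smooth
  force-proportional fluctuations (12% RMS, 20-ms correlation), and (iv)
  white sensor noise (0.02 V). Items (i)–(iii) are not decoration: without
  within- and between-trial force variability the force values at adjacent
  52-ms lags are ≈ 0.97-collinear and no fitter could recover per-lag
  coefficients. FO is the first threshold crossing (10% of the lowest
  target) sustained for 50 ms — the sustain requirement keeps a single >5σ
  noise sample from triggering onset; on a noiseless linear ramp of slope s
  the detected time is exactly t₀ + θ/s.
* **GLM spikes.** Sequential Bernoulli draws per 4-ms bin from the encoding
  model itself, with the history term computed causally from the spikes
  already drawn in the trial. Probabilities are clamped to
  (10⁻⁶, 1−10⁻⁶) with the clamp count reported. The default cohort
  (`sample_glm_cohort`) draws baseline rates uniformly in 5–30 spikes/s,
  refractory-dominated history weights, force tuning at 1–2 random lags,
  and null gape/interaction weights — the configuration under which the
  force-removed vs. gape-removed asymmetry has a known answer.
* **Latent populations.** Per-neuron rates are a baseline plus smooth random
  latent components, each projected exactly onto one marginalization and
  scaled so the marginalization variance fractions hit their targets
  (default 0.5/0.2/0.2/0.1); the realized fractions of the final (rectified)
  rate tensor are stored as ground truth, both raw and after the 50-ms
  analysis smoothing (`smoothed_fraction_truth`) — smoothing attenuates fast
  temporal structure and can shift the fractions by a few points, so the
  smoothed values are the matched estimand for the pipeline's estimates. Spikes are Poisson per 4-ms bin
  (optionally clipped to Bernoulli) with small Gaussian rate jitter. Spike
  history is deliberately omitted here: dPCA operates on trial-averaged
  rates, and history would confound the variance-fraction ground truth.
  The `ordered` option builds a marginalization from equally spaced class
  offsets along a single latent axis — the "well-separated" regime in which
  a first-component classifier should approach ceiling; with unordered
  random templates two classes can be nearly degenerate along the first
  component, which caps 1-D accuracy well below 1 even at high signal (a
  behavior real populations also show).

What the generator does **not** emulate: correlated noise across neurons,
non-Poisson count dispersion at the population stage, electrode/sorting
artifacts, behavioral failures (all trials succeed by default), or
session-scale nonstationarity. Passing tests therefore establish that the
estimators recover the truth under the stated generative assumptions — not
that real recordings satisfy those assumptions.

## Problem sizes and tolerances in the test suite

Simulation sizes were chosen as the smallest at which each estimator is
well-identified: coefficient recovery uses 50 neurons × ~207 trials × 250
bins (pooled truth-vs-estimate correlation ≥ 0.9); variance-fraction
recovery uses 18 neurons × 24 trials/condition (Poisson noise biases the
fractions by ~3 points at 12 trials/condition and ~1–2 at 24); decoding
calibration uses 500 shuffles with reduced CV repetitions (nominal per-bin
p = 0.002; the reduced-repetition null is conservative). Monte-Carlo
assertions use 3-SE bands or bounds with explicit slack; algebraic
identities (marginalization additivity/orthogonality, the dPCA→PCA limit)
are asserted at 10⁻⁸ or machine precision.

## Known limitations

* The full-model force/interaction coefficients remain the least-identified
  quantities; at fewer than ~100 trials their standard errors dominate and
  the preferred-lag analysis excludes many neurons (as it should).
* The decoder uses only the *first* component per marginalization, so
  class layouts that fold onto one axis (e.g., class 1 ≈ class 2) cap its
  accuracy regardless of population size.
* Variance fractions estimated from few trials are biased toward the
  higher-dimensional marginalizations (interaction) because trial-noise
  variance spreads across all of them; no noise correction is applied.
* Kruskal–Wallis/chi-squared cohort comparisons assume independent neurons,
  which simultaneous recordings violate in principle.
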