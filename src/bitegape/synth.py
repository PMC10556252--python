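"""Synthetic incisor-biting sessions with known ground truth.

The generator emulates the 3-gape × 3-force task: each trial presents one of
three static gape distances (defaults 11/14/17 mm, the larger subject's
values) and one of three required bite-force levels, with the force trace
rising along a smooth logistic ramp to a level proportional to the required
level and holding at target. Force onset (FO) is detected as the first
threshold crossing (10% of the lowest target). Spike trains come from either

* ``simulate_spikes_glm`` — a sequential Bernoulli draw per 4-ms bin from the
  same logit-link model the encoding stage fits, using known coefficients
  (spike history enters causally through the raised-cosine bases); or
* ``simulate_population_latent`` — Poisson spiking around per-neuron rate
  tensors built from smooth latent templates with controlled variance
  fractions per dPCA marginalization (no history: rates only, so the
  marginalization ground truth stays exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import AREAS, DEFAULT_BIN_WIDTH, DEFAULT_WINDOW, SpikeTrainSet, TrialTable
from .dpca import marginal_variance_fractions, marginalize
from .glm import LagGrid, RaisedCosineBasis, make_basis


@dataclass
class TaskSpec:
    """Parameters of a synthetic session (defaults mirror the task design)."""

    gapes_mm: tuple = (11.0, 14.0, 17.0)
    force_targets: tuple = (1.0, 2.0, 3.0)   # volts at the strain gauge
    trials_per_condition: int = 10
    trial_order: str = "randomized"          # or "blocked" (by gape)
    fo_jitter_s: float = 0.05
    seed: int = 0
    trace_duration_s: float = 3.0
    fo_nominal_s: float = 1.2
    sample_rate_hz: float = 1000.0
    ramp_tau_s: float = 0.08
    ramp_tau_jitter: float = 0.3             # lognormal sd of per-trial tau
    noise_sd: float = 0.02
    fluct_sd_rel: float = 0.12               # force-proportional fluctuation
    fluct_tau_s: float = 0.02                # its correlation time
    overshoot_range: tuple = (0.05, 0.35)    # rel. overshoot past target
    overshoot_freq_hz: tuple = (3.5, 6.0)    # ringing frequency range
    overshoot_decay_s: float = 0.2
    fo_threshold_frac: float = 0.1           # of the lowest force target

    def __post_init__(self) -> None:
        if len(self.gapes_mm) != 3 or len(self.force_targets) != 3:
            raise ValueError("task requires 3 gapes x 3 force levels")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.trial_order not in ("randomized", "blocked"):
            raise ValueError(f"unknown trial_order {self.trial_order!r}")


def detect_force_onset(trace: np.ndarray, sample_rate_hz: float,
                       threshold: float, min_hold_s: float = 0.05) -> float:
    """Time of the first upward threshold crossing sustained for at least
    ``min_hold_s`` (so isolated noise excursions do not trigger), linearly
    interpolated between samples: a noiseless linear ramp of slope s starting
    at t0 gives exactly t0 + threshold/s."""
    trace = np.asarray(trace, dtype=float)
    above = trace >= threshold
    if not above.any():
        raise ValueError("trace never reaches the force-onset threshold")
    need = max(1, int(round(min_hold_s * sample_rate_hz)))
    run = np.convolve(above.astype(int), np.ones(need, dtype=int))[need - 1:]
    sustained = np.flatnonzero(run == need)  # start indices of full runs
    if sustained.size == 0:
        raise ValueError("no sustained crossing of the force-onset threshold")
    i = int(sustained[0])
    if i == 0:
        return 0.0
    frac = (threshold - trace[i - 1]) / (trace[i] - trace[i - 1])
    return (i - 1 + frac) / sample_rate_hz


def generate_trials(spec: TaskSpec) -> TrialTable:
    """Build a balanced trial table with force traces and detected FO times.

    Blocked ordering groups trials by gape (force levels shuffled within each
    block, as in the blocked subject); randomized interleaves all conditions.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = [(g, f) for g in (1, 2, 3) for f in (1, 2, 3)]
    order: list[tuple[int, int]] = []
    if spec.trial_order == "blocked":
        for g in rng.permutation([1, 2, 3]):
            block = [(int(g), f) for f in (1, 2, 3)
                     for _ in range(spec.trials_per_condition)]
            rng.shuffle(block)
            order.extend(block)
    else:
        order = [c for c in conditions for _ in range(spec.trials_per_condition)]
        rng.shuffle(order)

    n_samp = int(round(spec.trace_duration_s * spec.sample_rate_hz))
    t_axis = np.arange(n_samp) / spec.sample_rate_hz
    threshold = spec.fo_threshold_frac * min(spec.force_targets)

    rows, force = [], {}
    for tid, (g, f) in enumerate(order):
        target = spec.force_targets[f - 1]
        t_mid = spec.fo_nominal_s + rng.uniform(-spec.fo_jitter_s,
                                                spec.fo_jitter_s)
        # logistic ramp: steeper (in absolute units) for higher targets,
        # per-trial steepness variability
        tau = spec.ramp_tau_s * np.exp(rng.normal(0.0, spec.ramp_tau_jitter))
        act = expit((t_axis - t_mid) / tau)
        ramp = target * act
        # overshoot past target that rings down during the hold (subjects
        # exceed the required level before settling)
        amp = rng.uniform(*spec.overshoot_range)
        freq = rng.uniform(*spec.overshoot_freq_hz)
        phase = rng.uniform(-0.3, 0.3)
        dt = np.clip(t_axis - t_mid, 0.0, None)
        osc = amp * np.exp(-dt / spec.overshoot_decay_s) \
            * np.cos(2 * np.pi * freq * dt + phase)
        # force-proportional smooth fluctuations (effort tremor)
        k = int(round(3 * spec.fluct_tau_s * spec.sample_rate_hz))
        kern = np.exp(-0.5 * (np.arange(-k, k + 1)
                              / (spec.fluct_tau_s * spec.sample_rate_hz)) ** 2)
        kern /= kern.sum()
        fl = np.convolve(rng.normal(size=n_samp), kern, mode="same")
        fl *= spec.fluct_sd_rel / max(fl.std(), 1e-12)
        trace = ramp * (1.0 + fl + osc * act) \
            + rng.normal(0.0, spec.noise_sd, n_samp)
        fo = detect_force_onset(trace, spec.sample_rate_hz, threshold)
        rows.append({"trial_id": tid, "gape_mm": spec.gapes_mm[g - 1],
                     "gape_index": g, "force_level": f, "fo_time_s": fo,
                     "success": True})
        force[tid] = trace
    table = pd.DataFrame(rows)
    return TrialTable(table, force, spec.sample_rate_hz)


@dataclass
class GroundTruthGLM:
    """True coefficients of one neuron's encoding model."""

    beta0: float
    betaH: np.ndarray            # 3 history weights (16/44/108 ms bases)
    betaG: float                 # per mm of gape
    betaF: np.ndarray            # 8 weights over the lag grid
    betaGF: np.ndarray           # 8 interaction weights
    area: str = "MIo"

    def vector(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.betaH, [self.betaG],
                               self.betaF, self.betaGF])


def sample_glm_cohort(n_neurons: int, seed: int = 0,
                      force_scale: float = 0.5, gape_scale: float = 0.0,
                      interaction_scale: float = 0.0,
                      history_weights=(-1.5, -0.4, -0.1),
                      rate_range_hz=(5.0, 30.0)) -> list[GroundTruthGLM]:
    """Draw a cohort of ground-truth neurons with moderate firing rates.

    Force tuning concentrates at one or two random lags per neuron (scaled by
    ``force_scale``); gape/interaction tuning default to null, matching the
    asymmetry probed by the force-removed vs. gape-removed comparison.
    """
    rng = np.random.default_rng(seed)
    areas = [AREAS[i % 3] for i in range(n_neurons)]
    cohort = []
    for i in range(n_neurons):
        rate = rng.uniform(*rate_range_hz)
        p_bin = rate * DEFAULT_BIN_WIDTH
        beta0 = float(np.log(p_bin / (1 - p_bin)))
        bH = np.asarray(history_weights, float) * rng.uniform(0.6, 1.4, 3)
        bF = np.zeros(8)
        hot = rng.choice(8, size=rng.integers(1, 3), replace=False)
        bF[hot] = force_scale * rng.uniform(0.5, 1.0, len(hot)) \
            * rng.choice([-1, 1], len(hot))
        bG = gape_scale * rng.normal()
        bGF = interaction_scale * rng.normal(size=8) / 10.0
        cohort.append(GroundTruthGLM(beta0, bH, bG, bF,
                                     np.asarray(bGF), areas[i]))
    return cohort


def simulate_spikes_glm(truths: list[GroundTruthGLM], trials: TrialTable,
                        seed: int = 0,
                        window: tuple[float, float] = DEFAULT_WINDOW,
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        basis: RaisedCosineBasis | None = None,
                        lags: LagGrid | None = None,
                        p_clip: float = 1e-6) -> tuple[SpikeTrainSet, int]:
    """Draw spikes per 4-ms bin from the logit model with the true betas.

    History is causal: each bin's history features are computed from the
    spikes already drawn in the same trial, filtered through the raised-cosine
    bases. Returns the spike set and the count of probability clamps
    (probabilities numerically outside (p_clip, 1 − p_clip)).
    """
    basis = basis or make_basis(bin_width=bin_width)
    lags = lags or LagGrid()
    n_bins = int(round((window[1] - window[0]) / bin_width))
    centers = window[0] + bin_width * (np.arange(n_bins) + 0.5)
    df = trials.trials
    tids = df["trial_id"].to_numpy().astype(int)
    gape = df["gape_mm"].to_numpy()
    fo = df["fo_time_s"].to_numpy()
    n_trials = len(tids)

    F = np.zeros((n_trials, n_bins, len(lags)))
    for i, (tid, t0) in enumerate(zip(tids, fo)):
        for k, tau in enumerate(lags.lags_s):
            F[i, :, k] = trials.force_at(int(tid), t0 + centers + tau)

    rng = np.random.default_rng(seed)
    n_hist = basis.values.shape[0]
    clamps = 0
    records = []
    for nid, tr in enumerate(truths):
        gape_c = gape - gape.mean()   # interaction uses centered gape,
        eta_ext = (tr.beta0           # mirroring the design-matrix builder
                   + tr.betaG * gape[:, None]
                   + F @ tr.betaF
                   + gape_c[:, None] * (F @ tr.betaGF))
        s = np.zeros((n_trials, n_bins), dtype=np.int8)
        # effective history kernel: betaH already mixed through the bases
        hk = basis.values @ tr.betaH                    # [n_hist]
        u = rng.random((n_trials, n_bins))
        for b in range(n_bins):
            lo = max(0, b - n_hist)
            if b > 0:
                past = s[:, lo:b].astype(float)
                hist = past @ hk[:b - lo][::-1]
            else:
                hist = 0.0
            p = expit(eta_ext[:, b] + hist)
            clipped = np.clip(p, p_clip, 1 - p_clip)
            clamps += int(np.sum(clipped != p))
            s[:, b] = u[:, b] < clipped
        rows = np.nonzero(s)
        times = fo[rows[0]] + centers[rows[1]]   # bin centers, safely in-bin
        for trial_i, t in zip(rows[0], times):
            records.append((nid, tr.area, tids[trial_i], t))
    sp = pd.DataFrame(records,
                      columns=["neuron_id", "area", "trial_id", "spike_time_s"])
    sp = sp.sort_values(["neuron_id", "trial_id", "spike_time_s"],
                        kind="mergesort").reset_index(drop=True)
    return SpikeTrainSet(sp), clamps


@dataclass
class PopulationLatentSpec:
    """Latent-population generator with target dPCA variance fractions."""

    n_neurons: int = 20
    fractions: dict = field(default_factory=lambda: {
        "time": 0.5, "gape": 0.2, "force": 0.2, "interaction": 0.1})
    signal_sd_hz: float = 8.0      # RMS of the summed latent signal, spikes/s
    baseline_hz: tuple = (8.0, 20.0)
    noise_sd_hz: float = 0.5       # trial-to-trial rate jitter
    template_sigma_s: float = 0.1  # temporal smoothness of latent templates
    n_templates: int = 3
    ordered: tuple = ()            # marginalizations built with equally
    bernoulli: bool = False        # spaced class offsets along one axis
    seed: int = 0                  # (well-separated, e.g. ("gape",))
    n_bins: int = 250

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()), float)
        if (vals < 0).any():
            raise ValueError("variance fractions must be non-negative")
        if vals.sum() > 1.0 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")


def _smooth_noise(rng, shape, sigma_bins):
    """White noise low-passed along the last axis (periodic-free truncated
    Gaussian), giving smooth random templates."""
    from .core import smooth_rates
    x = rng.normal(size=shape)
    return smooth_rates(x, sigma_bins, 1.0)


def latent_rate_tensor(spec: PopulationLatentSpec):
    """Construct the noiseless rate tensor [neuron, 3, 3, time] plus its
    realized per-marginalization variance fractions (after rectification)."""
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_neurons, spec.n_bins
    sigma_bins = spec.template_sigma_s / DEFAULT_BIN_WIDTH
    signal = np.zeros((n, 3, 3, t))
    frac_items = [(k, v) for k, v in spec.fractions.items() if v > 0]
    offsets = np.array([-1.0, 0.0, 1.0])
    for phi, frac in frac_items:
        comp = np.zeros((n, 3, 3, t))
        if phi in spec.ordered and phi in ("gape", "force"):
            # single latent axis with equally spaced class offsets: classes
            # stay collinear and well separated on the first component
            course = np.abs(_smooth_noise(rng, (t,), sigma_bins)) + 0.5
            loadings = rng.normal(size=n)
            shape = (offsets[:, None, None] * course[None, None, :]
                     if phi == "gape" else
                     offsets[None, :, None] * course[None, None, :])
            shape = np.broadcast_to(shape, (3, 3, t))
            comp = loadings[:, None, None, None] * shape[None]
        else:
            for _ in range(spec.n_templates):
                template = _smooth_noise(rng, (3, 3, t), sigma_bins)
                loadings = rng.normal(size=n)
                comp += loadings[:, None, None, None] * template[None]
        part = marginalize(comp - comp.mean(axis=(1, 2, 3), keepdims=True))[phi]
        power = float((part ** 2).sum())
        if power > 0:
            comp_scaled = part / np.sqrt(power)
            signal += comp_scaled * np.sqrt(frac)
    # scale summed signal to the requested RMS
    rms = np.sqrt((signal ** 2).mean())
    if rms > 0:
        signal *= spec.signal_sd_hz / rms
    baseline = rng.uniform(*spec.baseline_hz, size=n)
    rates = baseline[:, None, None, None] + signal
    clipped = float((rates < 0).mean())
    rates = np.clip(rates, 0.0, None)
    centered = rates - rates.mean(axis=(1, 2, 3), keepdims=True)
    realized = marginal_variance_fractions(centered)
    return rates, realized, clipped


def smoothed_fraction_truth(rates: np.ndarray, kernel_sigma: float = 0.05,
                            bin_width: float = DEFAULT_BIN_WIDTH):
    """Realized variance fractions of the rate tensor after the analysis
    smoothing kernel — the estimand seen by a pipeline that smooths rates
    (a 50-ms kernel attenuates fast temporal structure and can shift the
    fractions by a few points relative to the raw tensor)."""
    from .core import smooth_rates
    sm = smooth_rates(rates, kernel_sigma, bin_width)
    sm = sm - sm.mean(axis=(1, 2, 3), keepdims=True)
    return marginal_variance_fractions(sm)


def simulate_population_latent(spec: PopulationLatentSpec, trials: TrialTable,
                               window: tuple[float, float] = DEFAULT_WINDOW,
                               bin_width: float = DEFAULT_BIN_WIDTH):
    """Poisson (or Bernoulli-clipped) spikes around the latent rate tensor.

    Returns (SpikeTrainSet, ground_truth) where ground_truth holds the
    noiseless rate tensor, its realized marginalization variance fractions,
    and the rectification clip fraction.
    """
    rates, realized, clipped = latent_rate_tensor(spec)
    rng = np.random.default_rng(spec.seed + 1)
    df = trials.trials
    centers = window[0] + bin_width * (np.arange(spec.n_bins) + 0.5)
    records = []
    areas = [AREAS[i % 3] for i in range(spec.n_neurons)]
    for _, row in df.iterrows():
        g, f = int(row["gape_index"]) - 1, int(row["force_level"]) - 1
        lam = rates[:, g, f, :] + rng.normal(
            0.0, spec.noise_sd_hz, (spec.n_neurons, spec.n_bins))
        lam = np.clip(lam, 0.0, None) * bin_width
        counts = rng.poisson(lam)
        if spec.bernoulli:
            counts = np.clip(counts, 0, 1)
        nz = np.nonzero(counts)
        for nid, b in zip(*nz):
            k = counts[nid, b]
            offs = np.sort(rng.uniform(0, bin_width, k))
            for o in offs:
                records.append((int(nid), areas[nid], int(row["trial_id"]),
                                float(row["fo_time_s"] + centers[b]
                                      - 0.5 * bin_width + o)))
    sp = pd.DataFrame(records,
                      columns=["neuron_id", "area", "trial_id", "spike_time_s"])
    sp = sp.sort_values(["neuron_id", "trial_id", "spike_time_s"],
                        kind="mergesort").reset_index(drop=True)
    truth = {"rates": rates, "realized_fractions": realized,
             "realized_fractions_smoothed": smoothed_fraction_truth(rates),
             "clip_fraction": clipped}
    return SpikeTrainSet(sp), truth
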