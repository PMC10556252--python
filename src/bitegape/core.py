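"""Core data model for the incisor-biting task: spike trains, trial metadata,
event-aligned binning, and peri-event time histograms (PETHs).

All neural analyses in this package operate on spike counts in 4-ms bins over a
±500 ms window aligned to force onset (FO), the time a trial's bite-force trace
first rises toward its target. Spike times are stored in seconds relative to
trial start; alignment subtracts each trial's ``fo_time_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

AREAS = ("MIo", "SIo", "CMA")

DEFAULT_WINDOW = (-0.5, 0.5)
DEFAULT_BIN_WIDTH = 0.004
PETH_SIGMA = 0.05

SPIKE_COLUMNS = ["neuron_id", "area", "trial_id", "spike_time_s"]
TRIAL_COLUMNS = ["trial_id", "gape_mm", "gape_index", "force_level",
                 "fo_time_s", "success"]


class SchemaError(ValueError):
    """A file or table violates the dataset schema."""


@dataclass
class SpikeTrainSet:
    """Spike events for a population of sorted single units.

    ``spikes`` holds one row per spike with columns ``neuron_id`` (int),
    ``area`` (one of MIo/SIo/CMA), ``trial_id`` (int), ``spike_time_s``
    (seconds from trial start). Within each (neuron, trial) the times must be
    strictly increasing.
    """

    spikes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPIKE_COLUMNS if c not in self.spikes.columns]
        if missing:
            raise SchemaError(f"spike table missing columns: {missing}")
        bad_area = set(self.spikes["area"].unique()) - set(AREAS)
        if bad_area:
            raise SchemaError(f"unknown area labels: {sorted(bad_area)}")

    def validate_sorted(self, policy: str = "reject") -> "SpikeTrainSet":
        """Check spike times are strictly increasing within (neuron, trial).

        ``policy='reject'`` raises on violation; ``policy='sort'`` returns a
        sorted copy (ties still rejected: duplicate times are unphysical for a
        sorted unit).
        """
        if policy not in ("reject", "sort"):
            raise ValueError(f"unknown policy {policy!r}")
        df = self.spikes.reset_index(drop=True)
        order = df.sort_values(["neuron_id", "trial_id", "spike_time_s"],
                               kind="mergesort").reset_index(drop=True)
        diffs = order.groupby(["neuron_id", "trial_id"])["spike_time_s"].diff()
        if (diffs.dropna() <= 0).any():
            raise SchemaError("duplicate spike times within a (neuron, trial)")
        already_sorted = df["spike_time_s"].equals(order["spike_time_s"]) and \
            df["trial_id"].equals(order["trial_id"]) and \
            df["neuron_id"].equals(order["neuron_id"])
        if not already_sorted and policy == "reject":
            raise SchemaError("spike times not sorted within trials "
                              "(pass policy='sort' to sort)")
        return SpikeTrainSet(order)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique(self.spikes["neuron_id"].to_numpy())

    def area_of(self) -> dict[int, str]:
        sub = self.spikes.drop_duplicates("neuron_id")
        return dict(zip(sub["neuron_id"].astype(int), sub["area"]))


@dataclass
class TrialTable:
    """Per-trial task parameters and bite-force traces.

    The task crosses 3 gape distances with 3 required force levels, so
    ``gape_mm`` takes exactly 3 distinct values and (gape_index, force_level)
    jointly define 9 trial types. ``fo_time_s`` is the force-onset time within
    the trace's span; ``force`` maps trial_id to a uniformly sampled trace.
    """

    trials: pd.DataFrame
    force: dict[int, np.ndarray] = field(default_factory=dict)
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SchemaError(f"trial table missing columns: {missing}")
        gapes = np.unique(self.trials["gape_mm"].to_numpy())
        if len(gapes) != 3:
            raise SchemaError(
                f"gape_mm must take exactly 3 distinct values, got {len(gapes)}")
        gi = self.trials["gape_index"].to_numpy()
        fl = self.trials["force_level"].to_numpy()
        if not (np.isin(gi, [1, 2, 3]).all() and np.isin(fl, [1, 2, 3]).all()):
            raise SchemaError("gape_index and force_level must be in 1..3")
        for tid, fo in zip(self.trials["trial_id"], self.trials["fo_time_s"]):
            tr = self.force.get(int(tid))
            if tr is not None and not (0.0 <= fo <= len(tr) / self.sample_rate_hz):
                raise SchemaError(f"trial {tid}: fo_time_s={fo} outside trace span")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.trials["trial_id"].to_numpy().astype(int)

    def row(self, trial_id: int) -> pd.Series:
        sel = self.trials[self.trials["trial_id"] == trial_id]
        if sel.empty:
            raise KeyError(f"unknown trial_id {trial_id}")
        return sel.iloc[0]

    def force_at(self, trial_id: int, times_s: np.ndarray) -> np.ndarray:
        """Force values at absolute trial times, linearly interpolated.

        Rejects times outside the trace span (no extrapolation) so that lagged
        force covariates never silently read invented data.
        """
        tr = self.force[int(trial_id)]
        t_axis = np.arange(len(tr)) / self.sample_rate_hz
        times_s = np.asarray(times_s, dtype=float)
        if times_s.min() < t_axis[0] or times_s.max() > t_axis[-1]:
            raise ValueError(
                f"trial {trial_id}: force trace (span {t_axis[0]:.3f}-"
                f"{t_axis[-1]:.3f} s) does not cover requested times "
                f"[{times_s.min():.3f}, {times_s.max():.3f}] s")
        return np.interp(times_s, t_axis, tr)

    def select(self, mask: np.ndarray) -> "TrialTable":
        sub = self.trials[mask].reset_index(drop=True)
        force = {int(t): self.force[int(t)] for t in sub["trial_id"]
                 if int(t) in self.force}
        return TrialTable(sub, force, self.sample_rate_hz)


@dataclass
class AlignedBinnedData:
    """Spike-count tensor [neuron, trial, bin] aligned to force onset.

    Bins are half-open ``[left, right)`` and left-aligned to the window start;
    with the default ±500 ms window and 4-ms bins there are exactly 250 bins.
    """

    counts: np.ndarray
    neuron_ids: np.ndarray
    trial_ids: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW
    bin_width_s: float = DEFAULT_BIN_WIDTH

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_edges(self) -> np.ndarray:
        return self.window[0] + self.bin_width_s * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window[0] + self.bin_width_s * (np.arange(self.n_bins) + 0.5)

    def neuron_index(self, neuron_id: int) -> int:
        idx = np.flatnonzero(self.neuron_ids == neuron_id)
        if idx.size == 0:
            raise KeyError(f"unknown neuron_id {neuron_id}")
        return int(idx[0])


def align_and_bin(spikes: SpikeTrainSet, trials: TrialTable,
                  window: tuple[float, float] = DEFAULT_WINDOW,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  include_failed: bool = False) -> AlignedBinnedData:
    """Align spikes to each trial's force onset and count them in fixed bins.

    A spike at time t (relative to trial start) in trial j falls in bin
    ``floor((t - fo_j - window[0]) / bin_width)``; spikes outside the window
    (including one exactly at the right edge) are dropped. By default only
    successful trials enter the tensor.
    """
    span = window[1] - window[0]
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"window span {span} not divisible by bin width {bin_width}")
    n_bins = int(round(n_bins))

    tt = trials if include_failed else trials.select(
        trials.trials["success"].to_numpy().astype(bool))
    if len(tt) == 0:
        raise ValueError("no trials to bin (all excluded?)")
    trial_ids = tt.trial_ids
    known = set(int(t) for t in trial_ids)
    all_known = set(int(t) for t in trials.trial_ids)
    sp = spikes.spikes
    bad = set(sp["trial_id"].astype(int).unique()) - all_known
    if bad:
        raise ValueError(f"spike records reference unknown trial_id(s): {sorted(bad)[:5]}")

    neuron_ids = spikes.neuron_ids
    n_pos = {int(n): i for i, n in enumerate(neuron_ids)}
    t_pos = {int(t): i for i, t in enumerate(trial_ids)}
    fo = tt.trials.set_index("trial_id")["fo_time_s"]

    counts = np.zeros((len(neuron_ids), len(trial_ids), n_bins), dtype=np.int64)
    tid_arr = sp["trial_id"].to_numpy().astype(int)
    in_tensor = np.array([t in t_pos for t in tid_arr])
    if in_tensor.any():
        sub = sp[in_tensor]
        tids = sub["trial_id"].to_numpy().astype(int)
        rel = sub["spike_time_s"].to_numpy() - fo.loc[tids].to_numpy()
        b = np.floor((rel - window[0]) / bin_width).astype(int)
        ok = (b >= 0) & (b < n_bins)
        rows = np.array([n_pos[int(n)] for n in sub["neuron_id"].to_numpy()[ok]])
        cols = np.array([t_pos[t] for t in tids[ok]])
        if rows.size:
            np.add.at(counts, (rows, cols, b[ok]), 1)
    return AlignedBinnedData(counts, neuron_ids, trial_ids, window, bin_width)


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    """Truncated (±3σ) Gaussian kernel, unnormalized tails handled by caller."""
    half = max(1, int(np.ceil(3 * sigma_bins)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def smooth_rates(rates: np.ndarray, sigma_s: float, bin_width: float) -> np.ndarray:
    """Smooth along the last axis with a truncated Gaussian, renormalizing at
    edges so a constant input maps to itself everywhere."""
    if sigma_s <= 0:
        return rates.astype(float)
    k = _gaussian_kernel(sigma_s / bin_width)
    n = rates.shape[-1]
    half = (len(k) - 1) // 2
    flat = rates.reshape(-1, n).astype(float)
    sm = np.apply_along_axis(
        lambda r: np.convolve(r, k, mode="full")[half:half + n], 1, flat)
    norm = np.convolve(np.ones(n), k, mode="full")[half:half + n]
    sm /= norm
    return sm.reshape(rates.shape)


@dataclass
class PETH:
    """Trial-averaged smoothed firing rates per condition group.

    ``rate[group]`` and ``sem[group]`` are [neuron, bin] arrays in spikes/s;
    SEM is ±1 standard error across trials of the smoothed per-trial rates.
    """

    time: np.ndarray
    rate: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_trials: dict[str, int]


def group_trials(trials: TrialTable, by: str) -> dict[str, np.ndarray]:
    """Partition trial ids by 'gape' (pooling over force), 'force' (pooling
    over gape), or 'type' (all 9 combinations)."""
    df = trials.trials
    groups: dict[str, np.ndarray] = {}
    if by == "gape":
        for g in (1, 2, 3):
            groups[f"G{g}"] = df.loc[df["gape_index"] == g, "trial_id"].to_numpy()
    elif by == "force":
        for f in (1, 2, 3):
            groups[f"F{f}"] = df.loc[df["force_level"] == f, "trial_id"].to_numpy()
    elif by == "type":
        for g in (1, 2, 3):
            for f in (1, 2, 3):
                sel = (df["gape_index"] == g) & (df["force_level"] == f)
                groups[f"G{g}F{f}"] = df.loc[sel, "trial_id"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {by!r}")
    return groups


def compute_peth(binned: AlignedBinnedData,
                 grouping: Mapping[str, Sequence[int]],
                 kernel_sigma: float = PETH_SIGMA) -> PETH:
    """PETH per neuron and trial group: smooth each trial's rate with a
    ``kernel_sigma`` Gaussian (default 50 ms), then mean ± SEM across trials."""
    t_pos = {int(t): i for i, t in enumerate(binned.trial_ids)}
    rate, sem, n_tr = {}, {}, {}
    for name, tids in grouping.items():
        tids = [int(t) for t in tids if int(t) in t_pos]
        if len(tids) == 0:
            raise ValueError(f"empty trial group {name!r}")
        idx = [t_pos[t] for t in tids]
        r = binned.counts[:, idx, :] / binned.bin_width_s
        r = smooth_rates(r, kernel_sigma, binned.bin_width_s)
        rate[name] = r.mean(axis=1)
        sem[name] = r.std(axis=1, ddof=1) / np.sqrt(len(idx)) if len(idx) > 1 \
            else np.zeros_like(rate[name])
        n_tr[name] = len(idx)
    return PETH(binned.bin_centers, rate, sem, n_tr)


# ---------------------------------------------------------------------------
# File I/O: CSV spike/trial tables + HDF5 force traces
# ---------------------------------------------------------------------------

def write_dataset(spikes: SpikeTrainSet, trials: TrialTable,
                  spikes_csv, trials_csv, force_h5) -> None:
    spikes.spikes.to_csv(spikes_csv, index=False)
    trials.trials.to_csv(trials_csv, index=False)
    with h5py.File(force_h5, "w") as h5:
        grp = h5.create_group("force")
        grp.attrs["sample_rate_hz"] = trials.sample_rate_hz
        for tid, tr in trials.force.items():
            grp.create_dataset(str(int(tid)), data=np.asarray(tr, dtype=float))


def read_dataset(spikes_csv, trials_csv, force_h5,
                 sort_policy: str = "reject") -> tuple[SpikeTrainSet, TrialTable]:
    try:
        sp = pd.read_csv(spikes_csv)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot parse spikes file: {exc}") from exc
    tr = pd.read_csv(trials_csv)
    spikes = SpikeTrainSet(sp).validate_sorted(policy=sort_policy)
    force: dict[int, np.ndarray] = {}
    rate = 1000.0
    with h5py.File(force_h5, "r") as h5:
        grp = h5["force"]
        rate = float(grp.attrs["sample_rate_hz"])
        for key in grp:
            force[int(key)] = grp[key][...]
    tr["success"] = tr["success"].astype(bool)
    return spikes, TrialTable(tr, force, rate)


def cache_binned(binned: AlignedBinnedData, force_h5) -> None:
    """Append the aligned count tensor to the dataset's HDF5 container."""
    with h5py.File(force_h5, "a") as h5:
        if "binned" in h5:
            del h5["binned"]
        grp = h5.create_group("binned")
        d = grp.create_dataset("counts", data=binned.counts)
        d.attrs["window"] = binned.window
        d.attrs["bin_width_s"] = binned.bin_width_s
        grp.create_dataset("neuron_ids", data=binned.neuron_ids)
        grp.create_dataset("trial_ids", data=binned.trial_ids)
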