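"""Time-resolved single-trial decoding from demixed components.

The first decoding axis of a target marginalization (gape, force, or their
interaction) serves as a fixed 1-D linear classifier. Accuracy is estimated
by stratified Monte-Carlo leave-group-out cross-validation: on each iteration
one trial per neuron per condition is held out, dPCA is refit on the training
average, held-out pseudo-trials are projected onto the axis, and each is
assigned per 50-ms time bin to the class with the nearest training-mean
projection. Chance is estimated by repeating the procedure with condition
labels permuted across trials (within neuron); a bin is significant when the
actual mean accuracy exceeds ALL shuffled accuracies — with 500 shuffles a
nominal p of 1/500 = 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dpca import ConditionTensor, marginalize

TARGET_CLASSES = {"gape": 3, "force": 3, "interaction": 9}


def nominal_p(n_shuffle: int) -> float:
    """Nominal per-bin p-value of the exceed-all rule with ``n_shuffle``
    shuffled curves."""
    if n_shuffle < 1:
        raise ValueError("need at least one shuffle")
    return 1.0 / n_shuffle


@dataclass
class DecodingResult:
    time: np.ndarray
    accuracy: np.ndarray          # mean accuracy per time bin
    null_accuracies: np.ndarray   # [n_shuffle, time bins]
    significant: np.ndarray       # accuracy > all nulls, per bin
    target: str
    n_cv: int
    n_shuffle: int

    @property
    def nominal_p(self) -> float:
        return nominal_p(self.n_shuffle)


def _rebin_time(arr: np.ndarray, bin_width_s: float, time_bin_s: float):
    """Average the trailing time axis into coarser bins (e.g. 4 ms → 50 ms).

    Trailing samples that do not fill a whole coarse bin are dropped.
    """
    factor = int(round(time_bin_s / bin_width_s))
    t = arr.shape[-1]
    n_out = t // factor
    trimmed = arr[..., :n_out * factor]
    return trimmed.reshape(*arr.shape[:-1], n_out, factor).mean(axis=-1), factor


def _first_axis(Xc: np.ndarray, target: str, lam_rel: float) -> np.ndarray:
    """First dPCA decoding axis of the target marginalization for a centered
    [neuron, 3, 3, time] training tensor (inlined minimal fit for speed)."""
    n = Xc.shape[0]
    X = Xc.reshape(n, -1)
    Xphi = marginalize(Xc)[target].reshape(n, -1)
    lam = lam_rel * float((X ** 2).sum()) / n
    K = X @ X.T + lam * np.eye(n)
    A = np.linalg.solve(K, X @ Xphi.T).T          # Xφ Xᵀ K⁻¹ (K symmetric)
    M = A @ X
    # top left singular vector of M, via eigendecomposition of small matrix
    u, _, _ = np.linalg.svd(M, full_matrices=False)
    return u[:, 0] @ A                            # decoder row, [neurons]


def _labels_for(target: str) -> np.ndarray:
    """Class label per (gape, force) cell, row-major over the 3×3 grid."""
    g, f = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if target == "gape":
        return g.ravel()
    if target == "force":
        return f.ravel()
    if target == "interaction":
        return (g * 3 + f).ravel()
    raise ValueError(f"unknown target {target!r}")


def decode_timecourse(tensor: ConditionTensor, target: str,
                      n_cv: int = 1000, n_shuffle: int = 500,
                      n_cv_per_shuffle: int | None = None,
                      time_bin: float = 0.05, reg: float = 1e-6,
                      seed: int = 0) -> DecodingResult:
    """Decode the target parameter over time with shuffle-based significance.

    ``n_cv_per_shuffle`` controls how many CV repetitions estimate each
    shuffled curve (default: n_cv // 10, at least 5); fewer repetitions make
    the null curves noisier and the exceed-all rule conservative.
    """
    if target not in TARGET_CLASSES:
        raise ValueError(f"unknown target {target!r}")
    R = tensor.trial                                  # [n, 3, 3, rep, t]
    if R.shape[3] < 2:
        raise ValueError("need >= 2 trials per condition to cross-validate")
    Rb, _ = _rebin_time(R, tensor.bin_width_s, time_bin)
    n, _, _, n_rep, T = Rb.shape
    edges_t = tensor.time[0] - tensor.bin_width_s / 2 \
        + time_bin * (np.arange(T) + 0.5)
    labels = _labels_for(target)
    rng = np.random.default_rng(seed)
    if n_cv_per_shuffle is None:
        n_cv_per_shuffle = max(5, n_cv // 10)

    def run_cv(data: np.ndarray, iters: int, rng_local) -> np.ndarray:
        acc = np.zeros(T)
        flat = data.reshape(n, 9, n_rep, T)
        for _ in range(iters):
            held = rng_local.integers(0, n_rep, size=(n, 9))
            test = np.take_along_axis(
                flat, held[:, :, None, None], axis=2)[:, :, 0, :]
            train_sum = flat.sum(axis=2) - test
            train = train_sum / (n_rep - 1)           # [n, 9, T]
            gm = train.mean(axis=(1, 2), keepdims=True)
            trainc = (train - gm).reshape(n, 3, 3, T)
            d = _first_axis(trainc, target, reg)
            proj_train = np.einsum("i,icr->cr", d, trainc.reshape(n, 9, T))
            proj_test = np.einsum("i,icr->cr", d, (test - gm).reshape(n, 9, T))
            # class centroids from training projections
            n_cls = TARGET_CLASSES[target]
            cent = np.zeros((n_cls, T))
            for c in range(n_cls):
                cent[c] = proj_train[labels == c].mean(axis=0)
            dist = np.abs(proj_test[:, None, :] - cent[None, :, :])
            pred = np.argmin(dist, axis=1)            # ties → lower class
            acc += (pred == labels[:, None]).mean(axis=0)
        return acc / iters

    accuracy = run_cv(Rb, n_cv, rng)

    nulls = np.zeros((n_shuffle, T))
    flat = Rb.reshape(n, 9 * n_rep, T)
    for s in range(n_shuffle):
        shuffled = np.empty_like(flat)
        for i in range(n):
            shuffled[i] = flat[i, rng.permutation(9 * n_rep)]
        nulls[s] = run_cv(shuffled.reshape(n, 3, 3, n_rep, T),
                          n_cv_per_shuffle, rng)

    significant = accuracy > nulls.max(axis=0)
    return DecodingResult(edges_t, accuracy, nulls, significant,
                          target, n_cv, n_shuffle)


def summarize_significance(result: DecodingResult):
    """Contiguous runs of significant bins as (t_start, t_end) intervals."""
    sig = np.asarray(result.significant, bool)
    half = np.median(np.diff(result.time)) / 2 if len(result.time) > 1 else 0.0
    intervals = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(result.time[start] - half),
                              float(result.time[i - 1] + half)))
            start = None
    if start is not None:
        intervals.append((float(result.time[start] - half),
                          float(result.time[-1] + half)))
    return intervals
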