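"""Demixed principal components analysis (dPCA) of population activity.

Trial-averaged smoothed firing rates X (neurons × gape × force × time) are
decomposed into additive marginalizations

    X − grand mean = X_T + X_G + X_F + X_I        (+ X_noise on single trials)

where X_T is the condition-independent time course, X_G the gape term (gape
main effect plus gape×time), X_F the force term, and X_I the gape×force
interaction (including its time course). For each marginalization φ, dPCA
finds decoder rows D_φ and encoder columns F_φ minimizing the loss

    L = Σ_φ ||X_φ − F_φ D_φ X||²  (+ ridge λ||F_φ D_φ||²)

via the closed-form reduced-rank regression: the full-rank ridge solution
A_φ = X_φ Xᵀ (X Xᵀ + λI)⁻¹ followed by rank truncation using the SVD of
A_φ X. Components are ordered by explained variance; per-component and
per-marginalization variance fractions mirror the usual bar/pie summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AlignedBinnedData, TrialTable, smooth_rates

PHIS = ("time", "gape", "force", "interaction")


@dataclass
class ConditionTensor:
    """Trial-averaged (and per-trial) smoothed rates on the 3×3 task grid.

    ``mean`` is [neuron, gape, force, time]; ``trial`` is the balanced
    per-trial tensor [neuron, gape, force, rep, time] used for decoding;
    ``grand_mean`` is the per-neuron mean over conditions and time.
    """

    mean: np.ndarray
    trial: np.ndarray
    grand_mean: np.ndarray
    time: np.ndarray
    neuron_ids: np.ndarray
    bin_width_s: float

    @property
    def centered(self) -> np.ndarray:
        return self.mean - self.grand_mean[:, None, None, None]

    @property
    def shape(self):
        return self.mean.shape


def build_condition_tensor(binned: AlignedBinnedData, trials: TrialTable,
                           kernel_sigma: float = 0.05) -> ConditionTensor:
    """Average smoothed single-trial rates within each of the 9 task
    conditions (same 50-ms Gaussian policy as the PETHs).

    The per-trial tensor is balanced by truncating every cell to the minimum
    per-cell trial count (trials taken in trial-id order, deterministically).
    """
    df = trials.trials.set_index("trial_id")
    gi = df.loc[binned.trial_ids, "gape_index"].to_numpy()
    fl = df.loc[binned.trial_ids, "force_level"].to_numpy()
    cells = {}
    for g in (1, 2, 3):
        for f in (1, 2, 3):
            idx = np.flatnonzero((gi == g) & (fl == f))
            if len(idx) < 2:
                raise ValueError(f"condition (gape={g}, force={f}) has "
                                 f"{len(idx)} trial(s); need >= 2")
            cells[(g, f)] = idx[np.argsort(binned.trial_ids[idx])]
    n_rep = min(len(v) for v in cells.values())
    n, _, t = binned.counts.shape
    rates = smooth_rates(binned.counts / binned.bin_width_s,
                         kernel_sigma, binned.bin_width_s)
    mean = np.zeros((n, 3, 3, t))
    trial = np.zeros((n, 3, 3, n_rep, t))
    for (g, f), idx in cells.items():
        mean[:, g - 1, f - 1] = rates[:, idx, :].mean(axis=1)
        trial[:, g - 1, f - 1] = rates[:, idx[:n_rep], :]
    grand = mean.mean(axis=(1, 2, 3))
    return ConditionTensor(mean, trial, grand, binned.bin_centers,
                           binned.neuron_ids, binned.bin_width_s)


def marginalize(Y: np.ndarray) -> dict[str, np.ndarray]:
    """Split a centered tensor Y[..., gape, force, time] into the four
    marginalizations, each broadcast back to the full shape.

    X_T is the mean over conditions; X_G pools the gape main effect with
    gape×time; X_F likewise for force; X_I is the remainder (gape×force and
    gape×force×time). The four terms sum to Y exactly and are mutually
    orthogonal projections.
    """
    if Y.ndim < 3:
        raise ValueError("expected [..., gape, force, time]")
    X_T = Y.mean(axis=(-3, -2), keepdims=True)
    X_G = Y.mean(axis=-2, keepdims=True) - X_T
    X_F = Y.mean(axis=-3, keepdims=True) - X_T
    X_I = Y - X_T - X_G - X_F
    bcast = np.broadcast_to
    return {"time": bcast(X_T, Y.shape).copy(),
            "gape": bcast(X_G, Y.shape).copy(),
            "force": bcast(X_F, Y.shape).copy(),
            "interaction": X_I}


def marginal_variance_fractions(Y: np.ndarray) -> dict[str, float]:
    """Fraction of total centered variance in each marginalization."""
    parts = marginalize(Y)
    tot = sum(float((v ** 2).sum()) for v in parts.values())
    if tot == 0:
        return {k: 0.0 for k in parts}
    return {k: float((v ** 2).sum()) / tot for k, v in parts.items()}


@dataclass
class DPCAComponent:
    phi: str
    index_in_phi: int
    decoder: np.ndarray   # [neurons]
    encoder: np.ndarray   # [neurons]
    variance: float       # ||f dᵀ X||² (unnormalized)
    variance_by_phi: dict[str, float] = field(default_factory=dict)


@dataclass
class DPCAResult:
    components: list[DPCAComponent]      # ordered by explained variance
    marginal_fractions: dict[str, float]  # the "pie": ||X_φ||² / Σ||X_φ||²
    total_variance: float                 # ||X||² (centered)
    loss: float
    loss_pca_baseline: float
    cumulative_dpca: np.ndarray
    cumulative_pca: np.ndarray
    reg: float
    X: np.ndarray                         # centered [neurons, conditions*time]
    shape: tuple

    def decoders(self, phi: str) -> np.ndarray:
        return np.array([c.decoder for c in self.components if c.phi == phi])

    def encoders(self, phi: str) -> np.ndarray:
        return np.array([c.encoder for c in self.components if c.phi == phi])


def _flatten(Y: np.ndarray) -> np.ndarray:
    return Y.reshape(Y.shape[0], -1)


def fit_dpca(tensor, n_components: int = 15, reg: float = 0.0,
             marginalizations: dict[str, np.ndarray] | None = None,
             per_phi_components: int | None = None) -> DPCAResult:
    """Fit demixed PCA to a (centered) condition tensor.

    ``tensor`` may be a ConditionTensor or a raw [neuron, gape, force, time]
    array (centered internally). ``reg`` is the ridge λ expressed relative to
    the mean per-neuron signal power (λ_abs = reg · ||X||²_F / N); 0 requests
    the unregularized solution and is rejected when X Xᵀ is rank-deficient.
    ``marginalizations`` overrides the default four-way task split with a
    custom additive decomposition (e.g. a single part equal to the whole
    centered tensor, in which limit dPCA with λ=0 reduces to PCA).
    """
    if isinstance(tensor, ConditionTensor):
        Y = tensor.centered
    else:
        Y = np.asarray(tensor, dtype=float)
        Y = Y - Y.mean(axis=(1, 2, 3), keepdims=True)
    n = Y.shape[0]
    X = _flatten(Y)
    parts = marginalize(Y) if marginalizations is None else marginalizations
    phis = tuple(parts)
    total_var = float((X ** 2).sum())
    XXt = X @ X.T
    lam = reg * total_var / n
    if lam == 0.0:
        rank = np.linalg.matrix_rank(XXt)
        if rank < n:
            raise np.linalg.LinAlgError(
                "X Xᵀ is rank-deficient; refit with reg > 0")
    K = XXt + lam * np.eye(n)
    per_phi = per_phi_components or min(n, n_components)

    comps: list[DPCAComponent] = []
    loss = 0.0
    for phi in phis:
        Xphi = _flatten(parts[phi])
        A = np.linalg.solve(K.T, (Xphi @ X.T).T).T   # Xφ Xᵀ K⁻¹
        M = A @ X
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        r = min(per_phi, (s > 1e-12 * max(s[0], 1e-300)).sum())
        for i in range(r):
            f = U[:, i]
            d = f @ A
            proj = np.outer(f, d @ X)
            var = float((proj ** 2).sum())
            by_phi = {q: float(((np.outer(f, d @ _flatten(parts[q]))) ** 2).sum())
                      for q in phis}
            comps.append(DPCAComponent(phi, i, d.copy(), f.copy(), var, by_phi))
        Fr = U[:, :r]
        Dr = Fr.T @ A
        loss += float(((Xphi - Fr @ (Dr @ X)) ** 2).sum())

    comps.sort(key=lambda c: -c.variance)
    comps = comps[:n_components] if n_components else comps

    # matched-rank PCA baseline: encoder = decoder = top principal axes of X
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    loss_pca = 0.0
    r = min(per_phi, U.shape[1])
    P = U[:, :r]
    PX = P @ (P.T @ X)
    for phi in phis:
        loss_pca += float(((_flatten(parts[phi]) - PX) ** 2).sum())

    n_curve = min(15, len(comps))
    cum_dpca = np.zeros(n_curve)
    recon = np.zeros_like(X)
    for i in range(n_curve):
        c = comps[i]
        recon = recon + np.outer(c.encoder, c.decoder @ X)
        cum_dpca[i] = 1.0 - ((X - recon) ** 2).sum() / total_var
    ev = s ** 2
    cum_pca = np.cumsum(ev)[:n_curve] / total_var

    tot = sum(float((v ** 2).sum()) for v in parts.values())
    fractions = {k: float((v ** 2).sum()) / tot if tot > 0 else 0.0
                 for k, v in parts.items()}
    return DPCAResult(comps, fractions, total_var, loss, loss_pca,
                      cum_dpca, cum_pca, reg, X, Y.shape)


def choose_regularization(tensor: ConditionTensor, grid=None,
                          n_components: int = 15, seed: int = 0) -> float:
    """Pick the ridge λ by split-half generalization: fit on the mean of one
    half of trials, score reconstruction of the other half's marginalized
    means. Returns the relative reg value (as taken by ``fit_dpca``)."""
    if grid is None:
        grid = [0.0] + list(np.logspace(-7, -1, 9))
    rng = np.random.default_rng(seed)
    n_rep = tensor.trial.shape[3]
    if n_rep < 2:
        raise ValueError("need >= 2 trials per condition to cross-validate λ")
    perm = rng.permutation(n_rep)
    half = n_rep // 2
    A = tensor.trial[:, :, :, perm[:half]].mean(axis=3)
    B = tensor.trial[:, :, :, perm[half:]].mean(axis=3)
    A = A - A.mean(axis=(1, 2, 3), keepdims=True)
    B = B - B.mean(axis=(1, 2, 3), keepdims=True)
    partsB = marginalize(B)
    XB = _flatten(B)
    best, best_err = grid[0], np.inf
    for reg in grid:
        try:
            res = fit_dpca(A, n_components=n_components, reg=reg)
        except np.linalg.LinAlgError:
            continue
        err = 0.0
        for phi in PHIS:
            D = res.decoders(phi)
            F = res.encoders(phi)
            if len(D) == 0:
                err += float((_flatten(partsB[phi]) ** 2).sum())
                continue
            err += float(((_flatten(partsB[phi]) - F.T @ (D @ XB)) ** 2).sum())
        if err < best_err:
            best, best_err = reg, err
    return float(best)


def variance_summary(result: DPCAResult) -> dict:
    """Tabular view of the variance accounting: per-marginalization totals
    (percent, the pie), per-component variance split by marginalization (the
    bars), and the first-15-component cumulative curves for dPCA and PCA."""
    import pandas as pd
    pie = {k: 100.0 * v for k, v in result.marginal_fractions.items()}
    rows = []
    for rank, c in enumerate(result.components, start=1):
        tot = sum(c.variance_by_phi.values())
        row = {"component": rank, "phi": c.phi,
               "variance_pct": 100.0 * c.variance / result.total_variance}
        for q in c.variance_by_phi:
            row[f"share_{q}"] = c.variance_by_phi[q] / tot if tot > 0 else 0.0
        rows.append(row)
    bars = pd.DataFrame(rows)
    return {"pie_pct": pie, "component_bars": bars,
            "cumulative_dpca": result.cumulative_dpca,
            "cumulative_pca": result.cumulative_pca}
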