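"""Point-process GLM encoding models of single-neuron spiking.

Each neuron's per-bin spike probability p_n(t) (4-ms bins, ±500 ms around
force onset) is modeled with a logit link:

    logit p_n(t) = beta0 + sum_j betaH_j H_j(t) + betaG G
                   + sum_k betaF_k F(t + tau_k) + sum_k betaGF_k G * F(t + tau_k)

where H_j are the neuron's own spike history filtered through raised-cosine
bases at short/medium/long timescales (16/44/108 ms), G is the trial's static
gape (mm), and F is the bite force sampled at 8 lags tau_k from −156 ms
(force leads spiking) to +208 ms (force lags spiking) in 52-ms steps —
1 gape + 8 force + 8 interaction = 17 extrinsic features. Models are fit by
maximum likelihood (IRLS with a tiny ridge for conditioning) under 10-fold
trial-level cross-validation and scored by AUROC on held-out trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .core import AlignedBinnedData, TrialTable

HISTORY_TIMESCALES_S = (0.016, 0.044, 0.108)
LAG_GRID_S = tuple(np.round(np.arange(-0.156, 0.2081, 0.052), 3))

GROUPS = ("history", "gape", "force", "interaction")

#: Model zoo: the full model and its reduced variants. Removing gape (or
#: force) also removes the gape×force interaction — an interaction does not
#: outlive its parent — while the *_only models are literal single-group
#: models (plus intercept).
MODEL_SPECS: dict[str, frozenset] = {
    "full": frozenset({"history", "gape", "force", "interaction"}),
    "no_gape": frozenset({"history", "force"}),
    "no_force": frozenset({"history", "gape"}),
    "no_force_no_gape": frozenset({"history"}),
    "force_only": frozenset({"force"}),
    "gape_only": frozenset({"gape"}),
    "interaction_only": frozenset({"interaction"}),
    "history_only": frozenset({"history"}),
    # extrinsic-only joint model used for force-removed/gape-removed scatter
    # comparisons (intrinsic covariates excluded)
    "force_gape": frozenset({"gape", "force"}),
}


@dataclass
class RaisedCosineBasis:
    """Raised-cosine spike-history filters b_j(tau) on the 4-ms lag grid.

    Basis j has center c_j = half-width w_j = timescale_j / 2, so its support
    is (0, timescale_j]: b_j(tau) = 0.5 (1 + cos(pi (tau − c_j)/w_j)) inside,
    0 outside. Lags start at one bin — no instantaneous self-coupling.
    """

    timescales_s: tuple
    bin_width_s: float
    lags_s: np.ndarray
    values: np.ndarray  # [n_lags, n_bases]

    @property
    def n_bases(self) -> int:
        return self.values.shape[1]


def make_basis(timescales=HISTORY_TIMESCALES_S,
               bin_width: float = 0.004) -> RaisedCosineBasis:
    ts = tuple(float(t) for t in timescales)
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"timescales must be strictly increasing, got {ts}")
    n_lags = int(round(max(ts) / bin_width))
    lags = bin_width * np.arange(1, n_lags + 1)
    vals = np.zeros((n_lags, len(ts)))
    for j, t_j in enumerate(ts):
        c = w = t_j / 2.0
        inside = np.abs(lags - c) <= w + 1e-12
        vals[inside, j] = 0.5 * (1.0 + np.cos(np.pi * (lags[inside] - c) / w))
    return RaisedCosineBasis(ts, bin_width, lags, vals)


@dataclass
class LagGrid:
    """Force-covariate lags; negative = force leads spiking."""

    lags_s: np.ndarray = field(
        default_factory=lambda: np.asarray(LAG_GRID_S))

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_s, dtype=float)
        steps = np.diff(lags)
        if len(lags) < 2 or not np.allclose(steps, steps[0], atol=1e-9):
            raise ValueError("lag grid must be an arithmetic sequence")
        self.lags_s = lags

    def __len__(self) -> int:
        return len(self.lags_s)


@dataclass
class DesignMatrix:
    """Per-(trial, bin) covariate rows for one neuron and one model spec."""

    X: np.ndarray            # [rows, p] incl. leading intercept column
    y: np.ndarray            # binarized spike indicator per row
    col_names: list[str]
    col_groups: list[str]    # "intercept" | "history" | "gape" | "force" | "interaction"
    trial_of_row: np.ndarray  # tensor trial index per row
    neuron_id: int
    spec_name: str
    clipped_fraction: float = 0.0

    @property
    def n_extrinsic(self) -> int:
        return sum(g in ("gape", "force", "interaction") for g in self.col_groups)


def history_features(spike_bins: np.ndarray, basis: RaisedCosineBasis) -> np.ndarray:
    """Filter binary spike trains [trial, bin] through the history bases.

    H_j(t) = sum_{tau>0} b_j(tau) s(t − tau), within-trial only; leading bins
    see zero-padded history.
    """
    n_trials, n_bins = spike_bins.shape
    out = np.zeros((n_trials, n_bins, basis.n_bases))
    s = spike_bins.astype(float)
    for j in range(basis.n_bases):
        k = basis.values[:, j]
        for lag_i, w in enumerate(k, start=1):
            if w == 0.0:
                continue
            out[:, lag_i:, j] += w * s[:, :-lag_i]
    return out


def build_design_matrix(binned: AlignedBinnedData, trials: TrialTable,
                        neuron_id: int, spec: str | frozenset,
                        basis: RaisedCosineBasis | None = None,
                        lags: LagGrid | None = None) -> DesignMatrix:
    """Assemble the design matrix for one neuron under a model spec.

    Force covariates are read from each trial's trace at bin-center time plus
    lag (negative lags read earlier force). The response is the binarized
    per-bin spike indicator.
    """
    groups = MODEL_SPECS[spec] if isinstance(spec, str) else frozenset(spec)
    name = spec if isinstance(spec, str) else "+".join(sorted(groups))
    basis = basis or make_basis(bin_width=binned.bin_width_s)
    lags = lags or LagGrid()

    n_idx = binned.neuron_index(neuron_id)
    counts = binned.counts[n_idx]                     # [trial, bin]
    spikes = (counts > 0).astype(np.int8)
    clipped = float((counts > 1).sum()) / counts.size
    n_trials, n_bins = counts.shape
    centers = binned.bin_centers

    cols: list[np.ndarray] = [np.ones(n_trials * n_bins)]
    names, groups_out = ["intercept"], ["intercept"]

    if "history" in groups:
        H = history_features(spikes, basis)
        for j, ts in enumerate(basis.timescales_s):
            cols.append(H[:, :, j].ravel())
            names.append(f"H_{int(round(ts * 1000))}ms")
            groups_out.append("history")

    gape = trials.trials.set_index("trial_id")["gape_mm"]
    gape_per_trial = gape.loc[binned.trial_ids].to_numpy()
    if "gape" in groups:
        cols.append(np.repeat(gape_per_trial, n_bins))
        names.append("gape")
        groups_out.append("gape")

    need_force = ("force" in groups) or ("interaction" in groups)
    if need_force:
        F = np.zeros((n_trials, n_bins, len(lags)))
        fo = trials.trials.set_index("trial_id")["fo_time_s"]
        for i, tid in enumerate(binned.trial_ids):
            t0 = float(fo.loc[int(tid)])
            for k, tau in enumerate(lags.lags_s):
                F[i, :, k] = trials.force_at(int(tid), t0 + centers + tau)
        if "force" in groups:
            for k, tau in enumerate(lags.lags_s):
                cols.append(F[:, :, k].ravel())
                names.append(f"F@{int(round(tau * 1000)):+d}ms")
                groups_out.append("force")
        if "interaction" in groups:
            # gape is centered inside the product: an uncentered G*F is nearly
            # collinear with F (gape spans a narrow range far from zero), which
            # leaves the force coefficients unidentifiable
            g_c = gape_per_trial - gape_per_trial.mean()
            for k, tau in enumerate(lags.lags_s):
                cols.append((g_c[:, None] * F[:, :, k]).ravel())
                names.append(f"GxF@{int(round(tau * 1000)):+d}ms")
                groups_out.append("interaction")

    X = np.column_stack(cols)
    y = spikes.ravel().astype(float)
    trial_of_row = np.repeat(np.arange(n_trials), n_bins)
    return DesignMatrix(X, y, names, groups_out, trial_of_row,
                        int(neuron_id), name, clipped)


# ---------------------------------------------------------------------------
# Bernoulli-logit maximum likelihood via IRLS
# ---------------------------------------------------------------------------

def irls_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                  tol: float = 1e-6, max_iter: int = 100):
    """IRLS for the Bernoulli-logit model with a tiny L2 ridge for
    conditioning. Convergence: penalized score inf-norm < tol within
    ``max_iter`` iterations (complete separation fails this and is flagged).

    Returns (beta, se, converged, n_iter); se from the inverse penalized
    Fisher information.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.clip(np.log((y.mean() + 1e-9) / (1 - y.mean() + 1e-9)), -10, 10)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu) - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        XtWX[np.diag_indices_from(XtWX)] += ridge
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        # halving for stability on ill-scaled starts
        ll0 = _penalized_ll(X, y, beta, ridge)
        scale = 1.0
        for _ in range(12):
            cand = beta + scale * step
            if _penalized_ll(X, y, cand, ridge) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X * w[:, None]).T @ X
    XtWX[np.diag_indices_from(XtWX)] += ridge
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    return beta, se, converged, it


def _penalized_ll(X, y, beta, ridge) -> float:
    eta = X @ beta
    # log-likelihood of Bernoulli-logit, numerically stable
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return ll - 0.5 * ridge * np.sum(beta ** 2)


def auroc(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve — the probability that a random spike bin
    outranks a random non-spike bin, ties counted half (Mann–Whitney)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: response contains a single class")
    return float(roc_auc_score(y, np.asarray(p_hat, dtype=float)))


def assign_folds(trials: TrialTable, trial_ids: np.ndarray, n_folds: int,
                 seed: int) -> np.ndarray:
    """Deterministic trial-level fold assignment, stratified by the 9 trial
    types so no fold is empty of any condition."""
    rng = np.random.default_rng(seed)
    df = trials.trials.set_index("trial_id")
    fold_of = np.full(len(trial_ids), -1, dtype=int)
    offset = 0
    for g in (1, 2, 3):
        for f in (1, 2, 3):
            sel = np.flatnonzero(
                (df.loc[trial_ids, "gape_index"].to_numpy() == g)
                & (df.loc[trial_ids, "force_level"].to_numpy() == f))
            rng.shuffle(sel)
            fold_of[sel] = (np.arange(len(sel)) + offset) % n_folds
            offset += len(sel)
    # trials of unseen types (possible with custom tables) dealt round-robin
    rest = np.flatnonzero(fold_of < 0)
    fold_of[rest] = np.arange(len(rest)) % n_folds
    return fold_of


@dataclass
class GLMFit:
    """Cross-validated fit of one model spec to one neuron."""

    neuron_id: int
    spec_name: str
    col_names: list[str]
    col_groups: list[str]
    coefs: np.ndarray        # [folds, p]
    ses: np.ndarray
    converged: np.ndarray    # [folds] bool
    fold_auroc: np.ndarray   # [folds]; NaN when undefined
    train_auroc: np.ndarray
    fold_of: np.ndarray
    full_coef: np.ndarray    # fit on all trials (for coefficient analyses)
    full_se: np.ndarray
    full_converged: bool

    @property
    def mean_auroc(self) -> float:
        ok = self.converged & np.isfinite(self.fold_auroc)
        return float(np.mean(self.fold_auroc[ok])) if ok.any() else np.nan

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    def coef_by_group(self, group: str, source: str = "full"):
        idx = [i for i, g in enumerate(self.col_groups) if g == group]
        if source == "full":
            return self.full_coef[idx], self.full_se[idx]
        return self.coefs[:, idx], self.ses[:, idx]


def fit_glm(design: DesignMatrix, n_folds: int = 10, seed: int = 0,
            fold_of: np.ndarray | None = None,
            trials: TrialTable | None = None,
            trial_ids: np.ndarray | None = None,
            ridge: float = 1e-6) -> GLMFit:
    """Fit a Bernoulli-logit GLM under trial-level K-fold cross-validation.

    ``fold_of`` (per tensor-trial fold labels) lets callers share one fold
    partition across model specs; otherwise it is derived from ``trials`` and
    ``seed`` by stratified assignment.
    """
    if design.y.sum() == 0:
        raise ValueError(f"neuron {design.neuron_id}: all-zero response")
    n_trials = design.trial_of_row.max() + 1
    if n_trials < n_folds:
        raise ValueError(f"need >= {n_folds} trials, got {n_trials}")
    if fold_of is None:
        if trials is None or trial_ids is None:
            raise ValueError("provide fold_of, or trials + trial_ids")
        fold_of = assign_folds(trials, trial_ids, n_folds, seed)

    p = design.X.shape[1]
    coefs = np.zeros((n_folds, p))
    ses = np.zeros((n_folds, p))
    conv = np.zeros(n_folds, dtype=bool)
    te_auc = np.full(n_folds, np.nan)
    tr_auc = np.full(n_folds, np.nan)
    row_fold = fold_of[design.trial_of_row]
    for k in range(n_folds):
        tr_rows = row_fold != k
        te_rows = ~tr_rows
        beta, se, ok, _ = irls_logistic(design.X[tr_rows], design.y[tr_rows],
                                        ridge=ridge)
        coefs[k], ses[k], conv[k] = beta, se, ok
        p_te = expit(design.X[te_rows] @ beta)
        p_tr = expit(design.X[tr_rows] @ beta)
        if len(np.unique(design.y[te_rows])) == 2:
            te_auc[k] = auroc(p_te, design.y[te_rows])
        if len(np.unique(design.y[tr_rows])) == 2:
            tr_auc[k] = auroc(p_tr, design.y[tr_rows])
    fbeta, fse, fok, _ = irls_logistic(design.X, design.y, ridge=ridge)
    return GLMFit(design.neuron_id, design.spec_name, design.col_names,
                  design.col_groups, coefs, ses, conv, te_auc, tr_auc,
                  fold_of, fbeta, fse, fok)


def run_model_zoo(binned: AlignedBinnedData, trials: TrialTable,
                  neuron_id: int, specs=None, n_folds: int = 10,
                  seed: int = 0, basis: RaisedCosineBasis | None = None,
                  lags: LagGrid | None = None) -> dict[str, GLMFit]:
    """Fit a set of model specs to one neuron with a shared fold partition."""
    specs = list(specs or MODEL_SPECS)
    fold_of = assign_folds(trials, binned.trial_ids, n_folds, seed)
    fits = {}
    for name in specs:
        dm = build_design_matrix(binned, trials, neuron_id, name, basis, lags)
        fits[name] = fit_glm(dm, n_folds=n_folds, fold_of=fold_of)
    return fits


def compare_models(fits_by_neuron: dict[int, dict[str, GLMFit]],
                   model_a: str, model_b: str):
    """Paired per-neuron AUROC comparison between two model specs.

    Returns (auroc_a, auroc_b, wilcoxon_stat, p) over neurons with defined
    mean AUROCs in both models; one-sided alternative a > b.
    """
    a, b = [], []
    for fits in fits_by_neuron.values():
        va, vb = fits[model_a].mean_auroc, fits[model_b].mean_auroc
        if np.isfinite(va) and np.isfinite(vb):
            a.append(va)
            b.append(vb)
    a, b = np.asarray(a), np.asarray(b)
    if len(a) < 5:
        raise ValueError("too few neurons for a paired comparison")
    diffs = a - b
    if np.allclose(diffs, 0):
        return a, b, 0.0, 1.0
    stat, pval = stats.wilcoxon(a, b, alternative="greater")
    return a, b, float(stat), float(pval)


def empirical_chance_auroc(design: DesignMatrix, n_folds: int = 10,
                           seed: int = 0, n_shuffles: int = 20,
                           fold_of: np.ndarray | None = None,
                           trials: TrialTable | None = None,
                           trial_ids: np.ndarray | None = None) -> float:
    """Empirical chance AUROC: mean cross-validated AUROC after shuffling the
    response at the trial level (breaking covariate–response association
    while preserving within-trial spike statistics). An alternative to the
    fixed 0.5 chance level for `classify_neuron`. Intended for extrinsic-only
    designs (force_only/gape_only): history columns are not recomputed for
    the shuffled responses."""
    rng = np.random.default_rng(seed)
    n_trials = design.trial_of_row.max() + 1
    rows_per_trial = design.X.shape[0] // n_trials
    y_trials = design.y.reshape(n_trials, rows_per_trial)
    scores = []
    for s in range(n_shuffles):
        perm = rng.permutation(n_trials)
        shuf = DesignMatrix(design.X, y_trials[perm].ravel(),
                            design.col_names, design.col_groups,
                            design.trial_of_row, design.neuron_id,
                            design.spec_name)
        fit = fit_glm(shuf, n_folds=n_folds, seed=seed, fold_of=fold_of,
                      trials=trials, trial_ids=trial_ids)
        if np.isfinite(fit.mean_auroc):
            scores.append(fit.mean_auroc)
    return float(np.mean(scores)) if scores else 0.5


def classify_neuron(force_only: GLMFit, gape_only: GLMFit,
                    chance: float = 0.5, min_converged: int = 6,
                    alpha: float = 0.05) -> dict:
    """Flag a neuron as force-/gape-related from its single-feature models.

    A neuron is included for a flag when that model converged in at least
    ``min_converged`` folds; the flag is set when a one-sided Wilcoxon
    signed-rank test of the fold AUROCs against chance gives p < alpha.
    """
    out = {}
    for label, fit in (("force", force_only), ("gape", gape_only)):
        included = fit.n_converged >= min_converged
        ok = fit.converged & np.isfinite(fit.fold_auroc)
        scores = fit.fold_auroc[ok]
        related = False
        pval = np.nan
        if included and len(scores) >= min_converged:
            d = scores - chance
            if np.any(d != 0):
                _, pval = stats.wilcoxon(d, alternative="greater")
                related = bool(pval < alpha)
            else:
                pval = 1.0
        out[f"{label}_included"] = bool(included)
        out[f"{label}_related"] = bool(related)
        out[f"{label}_p"] = float(pval) if np.isfinite(pval) else np.nan
    out["included"] = out["force_included"] and out["gape_included"]
    return out


def preferred_force_lag(force_only: GLMFit, lags: LagGrid | None = None,
                        alpha: float = 0.05) -> float | None:
    """The lag whose force coefficient is largest in magnitude among
    coefficients significantly different from zero (Wald z, two-sided
    p < alpha). Returns None when no lag is significant. Ties break toward
    the most negative (force-leading) lag.
    """
    lags = lags or LagGrid()
    beta, se = force_only.coef_by_group("force")
    if len(beta) != len(lags):
        raise ValueError("force-only fit does not match the lag grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    sig = pvals < alpha
    if not sig.any():
        return None
    mags = np.where(sig, np.abs(beta), -np.inf)
    best = np.max(mags)
    cand = np.flatnonzero(mags >= best - 1e-12)
    return float(lags.lags_s[cand[0]])  # grid is ascending: first = most negative


def lag_distribution(force_fits: dict[int, GLMFit], areas: dict[int, str],
                     lags: LagGrid | None = None, alpha: float = 0.05):
    """Preferred-lag distribution across neurons with per-area medians."""
    import pandas as pd
    rows = []
    excluded = 0
    for nid, fit in force_fits.items():
        tau = preferred_force_lag(fit, lags, alpha)
        if tau is None:
            excluded += 1
            continue
        rows.append({"neuron_id": nid, "area": areas[nid], "lag_s": tau})
    df = pd.DataFrame(rows, columns=["neuron_id", "area", "lag_s"])
    medians = df.groupby("area")["lag_s"].median().to_dict() if len(df) else {}
    return df, medians, excluded


def compare_history_timescales(full_fits: dict[int, GLMFit],
                               areas: dict[int, str] | None = None) -> dict:
    """Compare |beta| across the 16/44/108-ms history timescales.

    Kruskal–Wallis omnibus over the three coefficient-magnitude samples
    (one value per neuron per timescale), then Bonferroni-corrected pairwise
    rank-sum follow-ups. When ``areas`` is given, run per area.
    """
    if areas is not None:
        out = {}
        for area in sorted(set(areas.values())):
            sub = {n: f for n, f in full_fits.items() if areas[n] == area}
            out[area] = compare_history_timescales(sub)
        return out
    if len(full_fits) < 3:
        raise ValueError("need at least 3 neurons to compare history timescales")
    mags = []
    for fit in full_fits.values():
        beta, _ = fit.coef_by_group("history")
        mags.append(np.abs(beta))
    mags = np.asarray(mags)           # [neuron, timescale]
    labels = [f"{int(round(t * 1000))}ms" for t in HISTORY_TIMESCALES_S]
    stat, p = stats.kruskal(*mags.T)
    pairs = {}
    n_pairs = mags.shape[1] * (mags.shape[1] - 1) // 2
    for i in range(mags.shape[1]):
        for j in range(i + 1, mags.shape[1]):
            _, pij = stats.ranksums(mags[:, i], mags[:, j])
            pairs[f"{labels[i]}_vs_{labels[j]}"] = min(1.0, pij * n_pairs)
    medians = dict(zip(labels, np.median(mags, axis=0)))
    return {"kw_stat": float(stat), "kw_p": float(p),
            "pairwise_bonferroni_p": pairs, "median_abs_beta": medians}


def single_lag_control(binned: AlignedBinnedData, trials: TrialTable,
                       neuron_id: int,
                       spike_times_s=(0.06, 0.08, 0.10, 0.12, 0.14, 0.16),
                       force_time_s: float = 0.10,
                       n_folds: int = 10, seed: int = 0,
                       ridge: float = 1e-6) -> dict[float, dict]:
    """Control analysis: one force value (at +100 ms post-FO) and the spike
    indicator at a single time point — six mini-GLMs per neuron, each compared
    with its force-removed and gape-removed reductions.

    Returns {spike_time: {"joint"|"no_force"|"no_gape": mean test AUROC}}.
    """
    n_idx = binned.neuron_index(neuron_id)
    edges = binned.bin_edges
    df = trials.trials.set_index("trial_id")
    gape = df.loc[binned.trial_ids, "gape_mm"].to_numpy()
    fo = df.loc[binned.trial_ids, "fo_time_s"].to_numpy()
    force = np.array([trials.force_at(int(t), np.array([f0 + force_time_s]))[0]
                      for t, f0 in zip(binned.trial_ids, fo)])
    fold_of = assign_folds(trials, binned.trial_ids, n_folds, seed)
    results: dict[float, dict] = {}
    designs = {
        "joint": np.column_stack([np.ones_like(gape), gape, force, gape * force]),
        "no_force": np.column_stack([np.ones_like(gape), gape]),
        "no_gape": np.column_stack([np.ones_like(gape), force]),
    }
    for t_spike in spike_times_s:
        b = int(np.searchsorted(edges, t_spike, side="right") - 1)
        if b < 0 or b >= binned.n_bins:
            raise ValueError(f"no bin at spike time {t_spike}")
        y = (binned.counts[n_idx, :, b] > 0).astype(float)
        res = {}
        for name, X in designs.items():
            aucs = []
            for k in range(n_folds):
                tr, te = fold_of != k, fold_of == k
                if len(np.unique(y[te])) < 2 or y[tr].sum() == 0:
                    continue
                beta, _, ok, _ = irls_logistic(X[tr], y[tr], ridge=ridge)
                if not ok:
                    continue
                aucs.append(auroc(expit(X[te] @ beta), y[te]))
            res[name] = float(np.mean(aucs)) if aucs else np.nan
        results[float(t_spike)] = res
    return results
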