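"""Cohort-level statistics and report generation.

Mirrors the population-level comparisons applied to the encoding results:
Kruskal–Wallis across cortical areas on mean AUROC with Bonferroni-corrected
pairwise follow-ups, chi-squared tests on proportions of force- vs.
gape-related neurons (pairwise between-area tests at alpha = 0.05/3), and a
figure-style report where every panel is backed by a CSV of plotted values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import AREAS
from .glm import GLMFit, classify_neuron


def build_cohort_table(fits_by_neuron: dict[int, dict[str, GLMFit]],
                       areas: dict[int, str]) -> pd.DataFrame:
    """Tidy long table: one row per (neuron, model) with mean AUROC,
    converged-fold count, and force/gape-related flags."""
    rows = []
    for nid, fits in fits_by_neuron.items():
        flags = {}
        if "force_only" in fits and "gape_only" in fits:
            flags = classify_neuron(fits["force_only"], fits["gape_only"])
        for model, fit in fits.items():
            rows.append({"neuron_id": nid, "area": areas[nid], "model": model,
                         "mean_auroc": fit.mean_auroc,
                         "converged_folds": fit.n_converged, **flags})
    if not rows:
        raise ValueError("empty cohort")
    return pd.DataFrame(rows)


def binomial_sem(p: float, n: int) -> float:
    """Standard error of a proportion under the binomial assumption."""
    if n < 1:
        raise ValueError("need n >= 1")
    return float(np.sqrt(p * (1.0 - p) / n))


def compare_across_areas(table: pd.DataFrame, model: str) -> dict:
    """Kruskal–Wallis across areas on mean AUROC for one model, plus
    Bonferroni-adjusted pairwise rank-sum follow-ups."""
    sub = table[(table["model"] == model) & table["mean_auroc"].notna()]
    present = [a for a in AREAS if (sub["area"] == a).any()]
    if len(present) < 2:
        raise ValueError(f"need >= 2 areas with data, got {present}")
    samples = [sub.loc[sub["area"] == a, "mean_auroc"].to_numpy()
               for a in present]
    stat, p = stats.kruskal(*samples)
    pairs = {}
    n_pairs = len(present) * (len(present) - 1) // 2
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            _, pij = stats.ranksums(samples[i], samples[j])
            pairs[f"{present[i]}_vs_{present[j]}"] = min(1.0, pij * n_pairs)
    return {"model": model, "areas": present, "kw_stat": float(stat),
            "kw_p": float(p), "pairwise_bonferroni_p": pairs,
            "medians": {a: float(np.median(s))
                        for a, s in zip(present, samples)}}


def _chi2_2x2(a_hit, a_n, b_hit, b_n, correction=False):
    table = np.array([[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]])
    if (table < 0).any():
        raise ValueError("negative counts")
    if table.sum(axis=1).min() == 0:
        raise ValueError("empty group in proportion test")
    if table.sum(axis=0).min() == 0:
        # all observations share one outcome in both groups: no association
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def compare_proportions(table: pd.DataFrame, correction: bool = False) -> dict:
    """Chi-squared tests on force- vs. gape-related proportions.

    Within each area: force-related vs. gape-related counts (is force
    predominance significant?). Between areas: pairwise tests per flag at the
    Bonferroni-adjusted threshold alpha = 0.05/3.
    """
    per = table.drop_duplicates("neuron_id")
    present = [a for a in AREAS if (per["area"] == a).any()]
    if not present:
        raise ValueError("empty cohort")
    counts = {}
    for a in present:
        sub = per[per["area"] == a]
        n_f = int(sub["force_included"].sum()) if "force_included" in sub else len(sub)
        n_g = int(sub["gape_included"].sum()) if "gape_included" in sub else len(sub)
        counts[a] = {"force_related": int(sub.get("force_related", pd.Series(dtype=bool)).sum()),
                     "force_n": n_f,
                     "gape_related": int(sub.get("gape_related", pd.Series(dtype=bool)).sum()),
                     "gape_n": n_g}
    within = {}
    for a, c in counts.items():
        stat, p = _chi2_2x2(c["force_related"], c["force_n"],
                            c["gape_related"], c["gape_n"], correction)
        within[a] = {"chi2": stat, "p": p,
                     "force_prop": c["force_related"] / max(c["force_n"], 1),
                     "gape_prop": c["gape_related"] / max(c["gape_n"], 1),
                     "force_sem": binomial_sem(
                         c["force_related"] / max(c["force_n"], 1),
                         max(c["force_n"], 1)),
                     "gape_sem": binomial_sem(
                         c["gape_related"] / max(c["gape_n"], 1),
                         max(c["gape_n"], 1))}
    between = {}
    adj_alpha = 0.05 / 3
    for flag in ("force", "gape"):
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                stat, p = _chi2_2x2(counts[a][f"{flag}_related"],
                                    counts[a][f"{flag}_n"],
                                    counts[b][f"{flag}_related"],
                                    counts[b][f"{flag}_n"], correction)
                between[f"{flag}:{a}_vs_{b}"] = {
                    "chi2": stat, "p": p, "significant": p < adj_alpha}
    return {"within_area": within, "between_area": between,
            "adjusted_alpha": adj_alpha, "counts": counts}


def report(outdir, peth=None, cohort_table: pd.DataFrame | None = None,
           lag_table: pd.DataFrame | None = None,
           variance_summary: dict | None = None,
           decoding_results: dict | None = None) -> list[str]:
    """Write figure-style summary panels, each backed by a CSV of the plotted
    values. Raises when nothing is provided; returns the files written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    provided = [x is not None for x in
                (peth, cohort_table, lag_table, variance_summary,
                 decoding_results)]
    if not any(provided):
        raise ValueError("report: no upstream results provided")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(fig, stem):
        fig.savefig(outdir / f"{stem}.png", dpi=110)
        plt.close(fig)
        written.append(f"{stem}.png")

    if peth is not None:
        rows = []
        for grp, r in peth.rate.items():
            for n in range(r.shape[0]):
                for t, (v, s) in enumerate(zip(r[n], peth.sem[grp][n])):
                    rows.append({"group": grp, "neuron": n,
                                 "time_s": peth.time[t], "rate_hz": v,
                                 "sem_hz": s})
        pd.DataFrame(rows).to_csv(outdir / "peth.csv", index=False)
        written.append("peth.csv")
        fig, ax = plt.subplots(figsize=(5, 3))
        for grp, r in peth.rate.items():
            ax.plot(peth.time, r.mean(axis=0), label=grp)
        ax.set(xlabel="time from FO (s)", ylabel="rate (spikes/s)")
        ax.legend(fontsize=7)
        save(fig, "peth")

    if cohort_table is not None:
        if cohort_table.empty:
            raise ValueError("report: empty cohort table")
        cohort_table.to_csv(outdir / "cohort_auroc.csv", index=False)
        written.append("cohort_auroc.csv")
        fig, ax = plt.subplots(figsize=(6, 3))
        models = sorted(cohort_table["model"].unique())
        data = [cohort_table.loc[cohort_table["model"] == m,
                                 "mean_auroc"].dropna() for m in models]
        ax.boxplot(data, tick_labels=models)
        ax.axhline(0.5, ls="--", c="gray")
        ax.set_ylabel("mean AUROC")
        ax.tick_params(axis="x", rotation=45, labelsize=7)
        fig.tight_layout()
        save(fig, "auroc_boxes")

    if lag_table is not None:
        lag_table.to_csv(outdir / "preferred_lags.csv", index=False)
        written.append("preferred_lags.csv")
        fig, ax = plt.subplots(figsize=(4, 3))
        for a in sorted(lag_table["area"].unique()):
            vals = lag_table.loc[lag_table["area"] == a, "lag_s"] * 1000
            ax.hist(vals, bins=np.arange(-182, 235, 52), alpha=0.5, label=a)
            ax.axvline(vals.median(), ls=":")
        ax.set(xlabel="preferred force lag (ms)", ylabel="neurons")
        ax.legend(fontsize=7)
        save(fig, "lag_histogram")

    if variance_summary is not None:
        pie = variance_summary["pie_pct"]
        pd.DataFrame([pie]).to_csv(outdir / "variance_pie.csv", index=False)
        variance_summary["component_bars"].to_csv(
            outdir / "variance_components.csv", index=False)
        written += ["variance_pie.csv", "variance_components.csv"]
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        axes[0].pie(list(pie.values()), labels=list(pie.keys()),
                    autopct="%.0f%%")
        bars = variance_summary["component_bars"]
        axes[1].bar(bars["component"], bars["variance_pct"])
        axes[1].set(xlabel="component", ylabel="% variance")
        fig.tight_layout()
        save(fig, "variance")

    if decoding_results is not None:
        for target, res in decoding_results.items():
            df = pd.DataFrame({"time_s": res.time, "accuracy": res.accuracy,
                               "null_max": res.null_accuracies.max(axis=0),
                               "significant": res.significant})
            df.to_csv(outdir / f"decoding_{target}.csv", index=False)
            written.append(f"decoding_{target}.csv")
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.plot(res.time, res.accuracy, label="accuracy")
            lo = np.percentile(res.null_accuracies, 0, axis=0)
            hi = res.null_accuracies.max(axis=0)
            ax.fill_between(res.time, lo, hi, color="gray", alpha=0.4,
                            label="shuffle null")
            ax.set(xlabel="time from FO (s)", ylabel="accuracy",
                   title=target)
            ax.legend(fontsize=7)
            fig.tight_layout()
            save(fig, f"decoding_{target}")
    return written
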