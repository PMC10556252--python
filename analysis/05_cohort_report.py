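"""Cohort statistics and figure-style report.

Compares encoding performance across cortical areas (Kruskal-Wallis with
Bonferroni follow-ups), tests force- vs gape-related proportions
(chi-squared, pairwise at alpha = 0.05/3), and renders the report panels
(PETHs, AUROC boxes, lag histograms, variance pie/bars, decoding curves),
each backed by a CSV of the plotted values, under results/report/.
"""

from pathlib import Path

import pandas as pd

from bitegape import cohort, core, decode, dpca, glm

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
OUT = RES / "report"


def main():
    table = pd.read_csv(RES / "encoding" / "cohort_table.csv")
    print("encoding performance across areas (joint force+gape model):")
    try:
        res = cohort.compare_across_areas(table, "force_gape")
        print(f"  Kruskal-Wallis p = {res['kw_p']:.3g}; medians "
              f"{ {a: round(m, 3) for a, m in res['medians'].items()} }")
    except ValueError as e:
        print(f"  skipped: {e}")
    props = cohort.compare_proportions(table)
    for area, w in props["within_area"].items():
        print(f"  {area}: force {100 * w['force_prop']:.0f}% vs gape "
              f"{100 * w['gape_prop']:.0f}% related (chi2 p = {w['p']:.2g})")

    spikes, trials = core.read_dataset(RES / "data" / "glm_spikes.csv",
                                       RES / "data" / "trials.csv",
                                       RES / "data" / "session.h5")
    binned = core.align_and_bin(spikes, trials)
    peth = core.compute_peth(binned, core.group_trials(trials, "gape"))
    lag_table = pd.read_csv(RES / "encoding" / "preferred_lags.csv")

    pop_spikes, pop_trials = core.read_dataset(
        RES / "data" / "population_spikes.csv",
        RES / "data" / "trials_population.csv",
        RES / "data" / "session_population.h5")
    ct = dpca.build_condition_tensor(
        core.align_and_bin(pop_spikes, pop_trials), pop_trials)
    dres = dpca.fit_dpca(ct, n_components=15, reg=1e-6)
    summ = dpca.variance_summary(dres)
    dec = decode.decode_timecourse(ct, "gape", n_cv=60, n_shuffle=60,
                                   n_cv_per_shuffle=5, seed=13)

    written = cohort.report(OUT, peth=peth, cohort_table=table,
                            lag_table=lag_table, variance_summary=summ,
                            decoding_results={"gape": dec})
    print(f"wrote {len(written)} report files to {OUT}")


if __name__ == "__main__":
    main()
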