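"""Decompose the simulated population into demixed components.

Builds the trial-averaged condition tensor from the latent-population
session, fits dPCA, and accounts variance by task parameter (time, gape,
force, gape x force interaction), comparing the recovered fractions with the
generator's ground truth. Writes variance tables under results/dpca/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bitegape import core, dpca

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "dpca"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spikes, trials = core.read_dataset(DATA / "population_spikes.csv",
                                       DATA / "trials_population.csv",
                                       DATA / "session_population.h5")
    binned = core.align_and_bin(spikes, trials)
    ct = dpca.build_condition_tensor(binned, trials)
    res = dpca.fit_dpca(ct, n_components=15, reg=1e-6)
    summ = dpca.variance_summary(res)

    truth = json.loads((DATA / "ground_truth.json").read_text())
    want = truth["population_fractions"]
    print("variance by task parameter (% of centered variance):")
    for phi, pct in summ["pie_pct"].items():
        print(f"  {phi:12s} fitted {pct:5.1f}%   ground truth "
              f"{100 * want[phi]:5.1f}%")
    pd.DataFrame([summ["pie_pct"]]).to_csv(OUT / "variance_pie.csv",
                                           index=False)
    summ["component_bars"].to_csv(OUT / "variance_components.csv",
                                  index=False)
    curves = pd.DataFrame({"component": np.arange(1, 16),
                           "cumulative_dpca": summ["cumulative_dpca"],
                           "cumulative_pca": summ["cumulative_pca"]})
    curves.to_csv(OUT / "cumulative_variance.csv", index=False)
    n70 = int(np.searchsorted(summ["cumulative_dpca"], 0.7) + 1)
    print(f"{n70} demixed components explain 70% of the population variance "
          f"(PCA curve dominates dPCA at every rank, as it must)")
    print(f"dPCA loss {res.loss:.3g} <= matched-rank PCA-axes baseline "
          f"{res.loss_pca_baseline:.3g}")


if __name__ == "__main__":
    main()
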