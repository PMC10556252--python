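"""Simulate a synthetic biting session with known ground truth.

Generates the 3-gape x 3-force task (randomized order), a GLM-driven cohort
of single neurons spread across MIo/SIo/CMA, and a latent population with
known dPCA variance fractions. Writes the datasets (CSV + HDF5) and the
ground-truth parameters under results/data/ for the downstream stages.
"""

import json
from pathlib import Path

import numpy as np

from bitegape import core, synth

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    task = synth.TaskSpec(trials_per_condition=15, trial_order="randomized",
                          seed=SEED)
    trials = synth.generate_trials(task)
    print(f"task: {len(trials)} trials, gapes {task.gapes_mm} mm, "
          f"force targets {task.force_targets} V")

    cohort = synth.sample_glm_cohort(18, seed=SEED + 1, force_scale=0.6)
    spikes, clamps = synth.simulate_spikes_glm(cohort, trials, seed=SEED + 2)
    core.write_dataset(spikes, trials, OUT / "glm_spikes.csv",
                       OUT / "trials.csv", OUT / "session.h5")
    rate = len(spikes.spikes) / (len(trials) * 1.0) / 18
    print(f"GLM cohort: 18 neurons, {len(spikes.spikes)} spikes "
          f"(~{rate:.1f} Hz in-window), {clamps} probability clamps")

    truth_json = {
        "neurons": [{"neuron_id": i, "area": t.area, "beta0": t.beta0,
                     "betaH": t.betaH.tolist(), "betaG": t.betaG,
                     "betaF": t.betaF.tolist(), "betaGF": t.betaGF.tolist()}
                    for i, t in enumerate(cohort)]}

    pop = synth.PopulationLatentSpec(n_neurons=18, seed=SEED + 3,
                                     signal_sd_hz=12.0, noise_sd_hz=0.3,
                                     baseline_hz=(15.0, 30.0))
    pop_spikes, pop_truth = synth.simulate_population_latent(pop, trials)
    core.write_dataset(pop_spikes, trials, OUT / "population_spikes.csv",
                       OUT / "trials_population.csv",
                       OUT / "session_population.h5")
    truth_json["population_fractions"] = {
        k: float(v) for k, v in pop_truth["realized_fractions"].items()}
    truth_json["population_clip_fraction"] = pop_truth["clip_fraction"]
    (OUT / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    print("latent population realized variance fractions:",
          {k: round(v, 3) for k, v in truth_json["population_fractions"].items()})
    print(f"wrote datasets to {OUT}")


if __name__ == "__main__":
    main()
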