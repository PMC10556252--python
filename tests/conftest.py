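"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from bitegape import core, glm, synth


@pytest.fixture(scope="session")
def small_trials():
    """Balanced 4-trials-per-condition session (36 trials)."""
    return synth.generate_trials(synth.TaskSpec(trials_per_condition=4, seed=11))


@pytest.fixture(scope="session")
def glm_session():
    """Force-tuned GLM cohort: 6 neurons, 12 trials/condition, binned."""
    trials = synth.generate_trials(synth.TaskSpec(trials_per_condition=12, seed=21))
    cohort = synth.sample_glm_cohort(6, seed=22, force_scale=0.6)
    spikes, _ = synth.simulate_spikes_glm(cohort, trials, seed=23)
    binned = core.align_and_bin(spikes, trials)
    return {"trials": trials, "cohort": cohort, "spikes": spikes,
            "binned": binned}


@pytest.fixture(scope="session")
def zoo_fits(glm_session):
    """Model-zoo fits (shared folds) for the 6-neuron session."""
    trials, binned = glm_session["trials"], glm_session["binned"]
    specs = ["full", "force_gape", "force_only", "gape_only", "history_only"]
    return {n: glm.run_model_zoo(binned, trials, n, specs=specs, seed=31)
            for n in range(6)}


@pytest.fixture(scope="session")
def latent_session():
    """Latent population with known marginalization variance fractions."""
    trials = synth.generate_trials(synth.TaskSpec(trials_per_condition=24, seed=41))
    spec = synth.PopulationLatentSpec(
        n_neurons=18, seed=42, signal_sd_hz=12.0, noise_sd_hz=0.3,
        baseline_hz=(15.0, 30.0))
    spikes, truth = synth.simulate_population_latent(spec, trials)
    binned = core.align_and_bin(spikes, trials)
    return {"trials": trials, "spec": spec, "truth": truth, "binned": binned}
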