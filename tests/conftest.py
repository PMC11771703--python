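"""Shared fixtures: small synthetic studies and epoch sets.

Session-scoped fixtures amortize the cost of epoch synthesis across tests;
everything is seeded, so the suite is deterministic.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from emopower.synthgen import (SimulationConfig, simulate_epochs,  # noqa: E402
                               simulate_study)


SMALL = dict(n_participants=6, n_stimuli=12, n_erotica=2, n_surgery=1,
             n_channels=20)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def scene_epochs(small_config, small_study):
    stimuli, profiles, ratings, _ = small_study
    return simulate_epochs(stimuli, profiles, "scene", small_config, seed=21,
                           trial_effects=ratings)


@pytest.fixture(scope="session")
def video_epochs(small_config, small_study):
    stimuli, profiles, ratings, _ = small_study
    return simulate_epochs(stimuli, profiles, "video", small_config, seed=22,
                           trial_effects=ratings)


def model1_dataset(seed, J=12, S=30, par_bar=5.0, sigma_par=3.0,
                   sigma_stim=1.5, sigma_bar=2.5, tau=0.5):
    """Single-trial data drawn exactly from the participant+stimulus model.

    One trial per participant x stimulus.  Returns ``(trials, truth)`` with
    the generating parameter vectors.
    """
    rng = np.random.default_rng(seed)
    b1 = rng.normal(par_bar, sigma_par, J)
    b2 = rng.normal(0.0, sigma_stim, S)
    sig = np.abs(rng.normal(sigma_bar, tau, J))
    par = np.repeat(np.arange(J), S)
    stim = np.tile(np.arange(S), J)
    y = b1[par] + b2[stim] + sig[par] * rng.standard_normal(J * S)
    trials = pd.DataFrame({"participant_id": par + 1, "stimulus_id": stim + 1,
                           "amplitude": y})
    truth = {"beta1": b1, "beta2": b2, "sigma": sig, "par_bar": par_bar,
             "sigma_par": sigma_par, "sigma_stim": sigma_stim}
    return trials, truth


def model2_dataset(seed, J=12, n_per=90, rho=-0.5, mu_amp=5.0, sd_mu_amp=2.0,
                   s_amp=3.0, s_aro=1.6):
    """Bivariate (amplitude, arousal) trials with a common true correlation."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(J):
        muA = rng.normal(mu_amp, sd_mu_amp)
        muR = rng.normal(5.0, 0.5)
        sA = abs(rng.normal(s_amp, 0.5))
        sR = abs(rng.normal(s_aro, 0.2))
        cov = rho * sA * sR
        x = rng.multivariate_normal([muA, muR], [[sA ** 2, cov], [cov, sR ** 2]],
                                    n_per)
        for a, r in x:
            rows.append((j + 1, a, int(np.clip(round(r), 1, 9))))
    return pd.DataFrame(rows, columns=["participant_id", "amplitude", "arousal"])
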