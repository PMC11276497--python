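import numpy as np
import pandas as pd
import pytest

import bindmpt as bm
from bindmpt.hier_fit import HierarchicalConfig, PosteriorDraws


@pytest.fixture(scope="session")
def dep_e1():
    return bm.load_model("dependence", "E1")


@pytest.fixture(scope="session")
def ind_e1():
    return bm.load_model("independence", "E1")


@pytest.fixture(scope="session")
def dep_e2():
    return bm.load_model("dependence", "E2")


@pytest.fixture(scope="session")
def small_counts(dep_e1):
    """Frequency table simulated from the dependence model at known truth."""
    truth = bm.SimulationTruth.from_probabilities(dep_e1, p_b=0.6, p_i=0.7)
    return bm.simulate_counts(dep_e1, truth, n_participants=15,
                              trials_per_condition=72, seed=41)


@pytest.fixture(scope="session")
def small_fit(dep_e1, small_counts):
    """A short but converged hierarchical fit shared across diagnostic tests."""
    cfg = HierarchicalConfig(n_chains=2, n_iter=1600, n_burnin=600, seed=42)
    return bm.fit_hierarchical(dep_e1, small_counts, cfg)


def stub_draws(theta, parameter_names, experiment="E1", model_name="dependence"):
    """Fabricate a PosteriorDraws carrying given probability-scale arrays.

    ``theta``: array (n_chains, n_draws, K).
    """
    theta = np.asarray(theta, float)
    c, s, k = theta.shape
    from scipy.special import ndtri

    return PosteriorDraws(
        model_name=model_name,
        experiment=experiment,
        parameter_names=tuple(parameter_names),
        condition_labels=("c",) * k,
        participants=[0],
        mu=ndtri(theta),
        theta=theta,
        deviance=np.zeros((c, s)),
        sigma=None,
        person_probit=ndtri(theta)[:, :1, None, :],
        person_probit_mean=ndtri(theta).mean(axis=(0, 1))[None, :],
        config=HierarchicalConfig(n_chains=max(c, 2), n_iter=s + 1, n_burnin=0, seed=0),
    )
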