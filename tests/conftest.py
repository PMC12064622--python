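"""Shared fixtures: simulated banks, studies and expensive session-scoped fits."""

import numpy as np
import pandas as pd
import pytest

from difverse.data import ResponseMatrix, StudyFrame
from difverse.grm import GradedResponseModel
from difverse.multiverse import GridConfig, MultiverseDIF
from difverse.simulate import (
    DIFSpec,
    GroupSpec,
    SimulationConfig,
    inject_dif,
    make_study_fixture,
    simulate_item_bank,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_bank():
    """12-item 5-category bank used as fixed truth in simulations."""
    return simulate_item_bank(SimulationConfig(n_items=12, n_categories=5, seed=777))


@pytest.fixture(scope="session")
def recovery_data():
    """20-item, n=2000 single-group study with its generating bank."""
    cfg = SimulationConfig(
        n_items=20, n_categories=5, groups=(GroupSpec("G", 2000),), seed=42
    )
    bank = simulate_item_bank(cfg)
    responses, study, theta = simulate_responses(bank, cfg)
    return bank, responses, study, theta


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """Marginal-ML fit of the recovery study (shared: it costs a few seconds)."""
    _, responses, _, _ = recovery_data
    return GradedResponseModel(responses).fit()


@pytest.fixture(scope="session")
def twogroup_dif_study(small_bank):
    """Two groups of 500 with +1 logit uniform DIF injected in I03."""
    dif = (DIFSpec("I03", "F", "uniform", 1.0),)
    cfg = SimulationConfig(
        n_items=12,
        n_categories=5,
        groups=(GroupSpec("R", 500), GroupSpec("F", 500)),
        seed=101,
        dif=dif,
    )
    true_params = inject_dif(small_bank, dif)
    responses, study, theta = simulate_responses(true_params, cfg)
    return responses, study, theta, true_params


@pytest.fixture(scope="session")
def study_fixture():
    """The full synthetic three-country study (3601 persons, 35 items)."""
    return make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def multiverse_results(study_fixture):
    """Canonical 272-cell multiverse run on the study fixture (~80 s)."""
    fx = study_fixture
    model = MultiverseDIF(
        fx.responses,
        fx.study,
        grid=GridConfig(groups=("USA", "Germany", "Argentina")),
        published_params=fx.params_reference,
        reference_group="USA",
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
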