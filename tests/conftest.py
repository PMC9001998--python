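import numpy as np
import pandas as pd
import pytest

from gridlong import LongitudinalGridModel, SimulationDesign, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """One scaled main-effects dataset shared across read-only tests."""
    design = SimulationDesign(setup=1, n=80, N=400, p=40, n_causal=4, h2=0.4)
    return simulate(design, seed=42)


@pytest.fixture(scope="session")
def small_model(small_sim):
    return LongitudinalGridModel(small_sim.phenotypes, small_sim.genotypes, grid=3)


@pytest.fixture
def toy_phenotypes():
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "b"],
            "time": [0.0, 1.0, 0.2, 0.5, 0.9],
            "value": [1.0, 2.0, 0.5, 1.5, 2.5],
        }
    )


@pytest.fixture
def toy_genotypes():
    return pd.DataFrame(
        {"g1": [0.0, 1.0], "g2": [2.0, 1.0]},
        index=pd.Index(["a", "b"], name="subject_id"),
    )
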