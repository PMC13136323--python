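import numpy as np
import pandas as pd
import pytest

from sigshift import SyntheticConfig, generate_trial, normalize


@pytest.fixture(scope="session")
def default_trial():
    """One trial at the study-like default configuration."""
    return generate_trial(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_norm(default_trial):
    return normalize(default_trial.muscle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def small_matrix():
    """4 metabolites x 6 samples raw matrix with unit protein."""
    from sigshift import MetaboliteMatrix

    rng = np.random.default_rng(5)
    vals = 2.0 ** rng.normal(10, 1, size=(4, 6))
    df = pd.DataFrame(vals, index=[f"M{i}" for i in range(4)], columns=[f"S{i}" for i in range(6)])
    prot = pd.Series(1.0, index=df.columns)
    return MetaboliteMatrix(intensities=df, protein_conc=prot, tissue="muscle")
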