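import numpy as np
import pandas as pd
import pytest

from dictox.synthetic import SyntheticStudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared (read-only) across tests."""
    cfg = SyntheticStudyConfig(n_compounds=150, seed=7)
    return generate_study(cfg)


@pytest.fixture()
def six_compound_dataset():
    """Hand-built labeled dataset: 3 DICTrank + 3 SIDER, one overlap."""
    dictrank = pd.DataFrame(
        {
            "key": ["k1", "k2", "k3"],
            "std_smiles": ["CCO", "CCN", "CCC"],
            "concern": ["most", "no", "less"],
            "label": [1, 0, 1],
            "source": ["DICTrank"] * 3,
        }
    )
    sider = pd.DataFrame(
        {
            "key": ["k2", "k4", "k5"],
            "std_smiles": ["CCN", "CCS", "CCF"],
            "concern": ["unknown"] * 3,
            "label": [1, 1, 0],
            "source": ["SIDER"] * 3,
        }
    )
    return dictrank, sider


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
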