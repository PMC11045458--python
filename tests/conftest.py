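import numpy as np
import pandas as pd
import pytest

from omic import ExpressionMatrix, Modality, SimulationSpec, State, simulate
from omic.preprocess import scale_features


def make_matrix(values, state=State.RAW, modality=Modality.RNA, prefix=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    prefix = prefix or ("gene" if Modality(modality) is Modality.RNA else "adt")
    return ExpressionMatrix(
        values=values,
        obs_ids=pd.Index([f"cell_{i}" for i in range(n)]),
        feature_ids=pd.Index([f"{prefix}_{j}" for j in range(m)]),
        state=state,
        modality=modality,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """Moderate simulated dataset with both RNA and ADT cluster signal."""
    return simulate(SimulationSpec(n_cells=400, n_genes=60, n_adts=8, n_clusters=3, seed=7))


@pytest.fixture(scope="session")
def small_scaled(small_bundle):
    X = scale_features(small_bundle.rna)
    Y = scale_features(small_bundle.adt)
    return X, Y, small_bundle
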