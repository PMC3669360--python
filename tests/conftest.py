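import numpy as np
import pandas as pd
import pytest

from cernet.matrix import ExpressionMatrix
from cernet.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 11)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture()
def small_matrix():
    """4 probes x 6 samples, two conditions in triplicate."""
    rng = np.random.default_rng(3)
    samples = [f"{c}_{i}" for c in ("parental", "resistant") for i in (1, 2, 3)]
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["parental"] * 3 + ["resistant"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    ).set_index("sample_id")
    values = pd.DataFrame(
        rng.normal(8, 1, size=(4, 6)),
        index=[f"P{i}" for i in range(4)],
        columns=samples,
    )
    return ExpressionMatrix(values=values, design=design)
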