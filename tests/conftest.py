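import numpy as np
import pandas as pd
import pytest

from dielnet.io import ExpressionMatrix
from dielnet.simulate import SynthConfig, generate_dataset

ZT = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 4)


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-gene two-species dataset with planted ground truth."""
    cfg = SynthConfig(n_genes=200, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_matrix():
    values = pd.DataFrame(
        [[10.0, 20.0], [30.0, 40.0]],
        index=["g1", "g2"],
        columns=["s1", "s2"],
    )
    meta = pd.DataFrame(
        {
            "species": ["sp", "sp"],
            "zt": [0.0, 12.0],
            "replicate": ["0", "0"],
            "dark": [False, True],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    lengths = pd.Series([1000.0, 2000.0], index=["g1", "g2"])
    return ExpressionMatrix(values, metadata=meta, lengths=lengths, unit="counts")
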