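import numpy as np
import pandas as pd
import pytest

from floromics import StageProfileTable


@pytest.fixture
def small_table() -> StageProfileTable:
    """3 compounds x (2 stages x 3 replicates), known values."""
    cols = pd.MultiIndex.from_product(
        [["S9", "S13"], ["r1", "r2", "r3"]], names=["stage", "replicate"]
    )
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 1.1, 0.9, 2.0, 2.2, 1.8],
                [5.0, 5.5, 4.5, 5.0, 4.8, 5.2],
                [0.2, 0.25, 0.15, 0.05, 0.04, 0.06],
            ]
        ),
        index=["alpha", "beta", "gamma"],
        columns=cols,
    )
    classes = pd.Series(
        ["amino acid", "carbohydrate", "hormone"], index=values.index
    )
    fw = pd.Series(30.0, index=cols)
    istd = pd.Series(1.0, index=cols)
    return StageProfileTable(values, classes=classes, fw_mg=fw, istd=istd)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
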