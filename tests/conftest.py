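import numpy as np
import pandas as pd
import pytest

from radiomet import METABOLITE, RADIOMICS, OmicsBlock


def make_block(values, kind=RADIOMICS, prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsBlock(
        pd.DataFrame(
            values,
            index=[f"S{i:02d}" for i in range(n)],
            columns=[f"{prefix}{j:02d}" for j in range(p)],
        ),
        kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blocks(rng):
    """Row-aligned 8x3 radiomics and 8x4 metabolite blocks."""
    x = make_block(rng.normal(size=(8, 3)), RADIOMICS, "rf")
    y = make_block(rng.normal(size=(8, 4)), METABOLITE, "C")
    return x, y
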