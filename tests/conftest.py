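import numpy as np
import pandas as pd
import pytest

import honeyvola as hv


@pytest.fixture(scope="session")
def summary():
    return hv.load_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20230122)


def make_sample_table(rng, group_sizes, p, means=None, scale=1.0, prefix="v"):
    """Random multi-group sample table with optional per-group mean shifts."""
    names = [f"{prefix}{j}" for j in range(p)]
    frames = []
    for gi, (g, n) in enumerate(group_sizes.items()):
        shift = 0.0 if means is None else means[gi]
        x = np.abs(rng.normal(loc=5.0 + shift, scale=scale, size=(n, p)))
        df = pd.DataFrame(x, columns=names)
        df.insert(0, "group", g)
        df.index = [f"{g}-{i}" for i in range(n)]
        frames.append(df)
    out = pd.concat(frames)
    out.index.name = "sample_id"
    return hv.SampleTable(out)


@pytest.fixture
def three_group_table(rng):
    """3 groups x 4 variables with real group separation."""
    return make_sample_table(
        rng, {"A": 8, "B": 9, "C": 7}, p=4, means=[0.0, 1.5, 3.0], scale=1.0
    )
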