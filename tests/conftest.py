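import numpy as np
import pandas as pd
import pytest

from ifrmi.ifis import AttributeSchema, MixedDataset, intuitionistic_fuzzify
from ifrmi.synthdata import random_ifis, worked_fixture


@pytest.fixture
def fixture_ifis():
    """3-sample hand-checkable IF information system."""
    return worked_fixture()


@pytest.fixture
def make_ifis():
    """Factory for small mixed datasets from a column dict + kinds."""

    def build(columns: dict, kinds: dict, decision: str = "d", lam: float = 1.0):
        schema = tuple(
            AttributeSchema(
                name,
                kinds.get(name, "numeric"),
                "decision" if name == decision else "conditional",
            )
            for name in columns
        )
        data = MixedDataset(frame=pd.DataFrame(columns), schema=schema)
        return intuitionistic_fuzzify(data, lam=lam)

    return build


@pytest.fixture
def random_system():
    """Seeded random IFIS factory for property tests."""

    def build(seed, n=8, m=4, **kw):
        return random_ifis(seed=seed, n=n, m=m, **kw)

    return build
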