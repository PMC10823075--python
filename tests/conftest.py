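import numpy as np
import pandas as pd
import pytest

from bayesboost.core_data import CATEGORICAL, NUMERIC, Schema, TabularDataset, Variable
from bayesboost.fixtures import make_cvd_like, make_toy_bn


@pytest.fixture(scope="session")
def toy_net():
    return make_toy_bn()


@pytest.fixture(scope="session")
def cvd_small():
    """A 4,000-row CVD-like dataset shared across read-only tests."""
    return make_cvd_like(4000, seed=11)


@pytest.fixture()
def tiny_schema():
    return Schema(
        variables=(
            Variable("gender", CATEGORICAL, ("F", "M")),
            Variable("age", NUMERIC, bounds=(20.0, 80.0)),
            Variable("stroke", CATEGORICAL, ("0", "1")),
        ),
        target_name="stroke",
        protected_name="gender",
    )


@pytest.fixture()
def tiny_dataset(tiny_schema):
    rng = np.random.default_rng(5)
    n = 200
    gender = rng.choice(["F", "M"], size=n)
    age = rng.uniform(20, 80, size=n)
    logit = -3.0 + 0.05 * (age - 50) + 0.5 * (gender == "M")
    stroke = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int).astype(str)
    frame = pd.DataFrame({"gender": gender, "age": age, "stroke": stroke})
    return TabularDataset(tiny_schema, frame)
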