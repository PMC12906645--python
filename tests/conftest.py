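import numpy as np
import pandas as pd
import pytest

from gradvote import FeatureTable, ScenarioSpec, generate, stratified_split


@pytest.fixture
def separable_table():
    """Linearly separable two-feature table: class 1 iff num0 > 0."""
    rng = np.random.default_rng(42)
    n = 120
    y = np.array([0, 1] * (n // 2))
    x0 = np.where(y == 1, 1.0, -1.0) + 0.1 * rng.normal(size=n)
    x1 = rng.normal(size=n)
    return FeatureTable(pd.DataFrame({"num0": x0, "num1": x1}), y)


@pytest.fixture
def balanced_table():
    """Moderately informative 300-instance synthetic table."""
    return generate(
        ScenarioSpec(
            n_instances=300,
            n_numeric=4,
            n_categorical=1,
            positive_fraction=0.4,
            class_separation=1.5,
            label_noise=0.0,
            seed=7,
        )
    )


@pytest.fixture
def balanced_split(balanced_table):
    from gradvote import encode_and_impute, normalize

    split = stratified_split(balanced_table, (0.6, 0.2, 0.2), seed=7)
    train_raw = split.train
    parts = {
        name: encode_and_impute(part, fit_on=train_raw)
        for name, part in split.parts().items()
    }
    fit = parts["train"]
    split.train = normalize(parts["train"], fit)
    split.val = normalize(parts["val"], fit)
    split.test = normalize(parts["test"], fit)
    return split
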