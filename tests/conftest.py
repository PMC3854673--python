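import numpy as np
import pandas as pd
import pytest

import twofilter as tf


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, feature_ids=None, sample_ids=None, scale="log"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    nf, ns = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(nf)]
    sample_ids = sample_ids or [f"s{j}" for j in range(ns)]
    return tf.ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), scale
    )


@pytest.fixture(scope="session")
def signal_cohort():
    """Default generator cohort (strong planted signal) plus its log matrix."""
    c = tf.generate(tf.GeneratorConfig(seed=11))
    return c, tf.floor_and_log(c.expression)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no informative features."""
    c = tf.generate(tf.GeneratorConfig(
        seed=12, effect_size=0.0, n_informative_up=0, n_informative_down=0,
        n_samples=60, n_features=400,
    ))
    return c, tf.floor_and_log(c.expression)
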