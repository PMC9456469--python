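import numpy as np
import pandas as pd
import pytest

from tfenrich.dea import ContrastSpec
from tfenrich.matrix import ExpressionMatrix
from tfenrich.synthetic import SimConfig, simulate_expression, simulate_ontology


@pytest.fixture(scope="session")
def contrast():
    return ContrastSpec(treatment_group="treatment", control_group="control")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_probes=800, n_go_terms=15, tf_fraction=0.2, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    matrix, truth = simulate_expression(small_config)
    dag, ann = simulate_ontology(small_config, truth)
    return matrix, truth, dag, ann


def make_matrix(values, groups=None, flags=None, scale="linear", **kw):
    """Build a small ExpressionMatrix from a dict of sample -> column values."""
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))]
    if groups is None:
        groups = {c: ("treatment" if c.startswith("t") else "control") for c in df.columns}
    flags_df = None
    if flags is not None:
        flags_df = pd.DataFrame(flags)
        flags_df.index = df.index
    return ExpressionMatrix(values=df, groups=groups, flags=flags_df, scale=scale, **kw)


@pytest.fixture
def log2_matrix_4v2():
    rng = np.random.default_rng(0)
    values = {
        **{f"c{i}": rng.normal(8, 1, 50) for i in range(4)},
        **{f"t{i}": rng.normal(8, 1, 50) for i in range(2)},
    }
    return make_matrix(values, scale="log2")
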