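import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import counts_to_tpm
from cernet.io import ExpressionMatrix
from cernet.model import CeRNAScreen
from cernet.simulate import generate_bundle, recovery_conditions

GROUPS_4 = {"s1": "LE", "s2": "LE", "s3": "HE", "s4": "HE"}


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 1.5, 2.5], [10.0, 20.0, 30.0, 40.0]],
        index=["G1", "G2", "G3"], columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, "tpm", dict(GROUPS_4))


@pytest.fixture(scope="session")
def recovery_bundle():
    return generate_bundle(recovery_conditions(0))


@pytest.fixture(scope="session")
def recovery_results(recovery_bundle):
    from cernet.model import screen_bundle

    return screen_bundle(recovery_bundle)


def random_matrix(rng, feature_prefix, n_features, samples, groups):
    vals = rng.gamma(2.0, 50.0, size=(n_features, len(samples)))
    df = pd.DataFrame(vals, index=[f"{feature_prefix}{i}" for i in range(n_features)],
                      columns=samples)
    return ExpressionMatrix(df, "tpm", dict(groups))
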