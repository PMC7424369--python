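import numpy as np
import pandas as pd
import pytest

from reokit.simulate import generate, scenario_suite


@pytest.fixture(scope="session")
def smoking_like():
    """Fixed-seed two-group cohort with 10 planted large-shift DEGs."""
    return generate(scenario_suite()["smoking-like"])


@pytest.fixture(scope="session")
def age_null():
    """Fixed-seed cohort with no planted effect and expression-independent ages."""
    return generate(scenario_suite()["age-null"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples with a shared strict ordering g_a > g_b > g_c."""
    return pd.DataFrame(
        {
            "s1": [9.0, 5.0, 1.0],
            "s2": [8.0, 4.0, 2.0],
            "s3": [7.0, 6.0, 3.0],
            "s4": [9.5, 5.5, 0.5],
        },
        index=pd.Index(["g_a", "g_b", "g_c"], name="gene_id"),
    )


def group_samples(meta: pd.DataFrame, label: str) -> list[str]:
    return list(meta.index[meta["group"] == label])
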