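import numpy as np
import pandas as pd
import pytest

from chdrisk import load_reference_cohort, load_reference_stratification


@pytest.fixture(scope="session")
def cohort():
    """Packaged reference procedure-outcome table (102 procedures)."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def reported():
    """Published per-procedure rates and risk categories for cross-checks."""
    return load_reference_stratification()


@pytest.fixture(scope="session")
def eb_fit(cohort):
    """One shared deterministic empirical-Bayes fit of the reference cohort."""
    from chdrisk import BinomialRandomEffects
    return BinomialRandomEffects(method="eb").fit(cohort)


@pytest.fixture
def tiny_table():
    return pd.DataFrame({
        "procedure": ["a", "b", "c", "d"],
        "cases": np.array([100, 40, 8, 2000]),
        "deaths": np.array([1, 4, 2, 30]),
    })
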