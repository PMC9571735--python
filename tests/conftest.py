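import numpy as np
import pandas as pd
import pytest

from podtree import CohortTable, GeneratorConfig, generate_cohort


def make_table(columns: dict, outcome) -> CohortTable:
    """Build a small cohort from plain columns (generic numeric cue specs)."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    df["pod"] = np.asarray(outcome, dtype=int)
    return CohortTable(df)


@pytest.fixture(scope="session")
def table1_cohort() -> CohortTable:
    """A calibrated synthetic cohort at the study's sample size."""
    return generate_cohort(GeneratorConfig(n=394, seed=20))


@pytest.fixture(scope="session")
def big_cohort() -> CohortTable:
    """A large calibrated cohort for Monte-Carlo checks of the generator."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=7))
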