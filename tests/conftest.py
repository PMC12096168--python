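import warnings

import numpy as np
import pandas as pd
import pytest

from healtheq import codebook as cb
from healtheq.data_model import SurveyTable
from healtheq.synthetic import generate, study_config

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*max_iter.*")


def make_table(rows: dict) -> SurveyTable:
    """Build a SurveyTable from a column dict (test helper)."""
    return SurveyTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_survey() -> SurveyTable:
    """1,000 respondents under the default study conditions, fixed seed."""
    table, _ = generate(study_config(n=1_000, seed=7))
    return table


@pytest.fixture(scope="session")
def medium_survey():
    """20,000 respondents + truth record (study conditions, fixed seed)."""
    return generate(study_config(n=20_000, seed=11))


def full_rows(n: int, seed: int = 0) -> dict:
    """Valid minimal columns for n respondents (uniform codes)."""
    rng = np.random.default_rng(seed)
    cols = {f: rng.choice(cb.CODE_SETS[f], size=n) for f in cb.FACTORS
            if f != "income_quintile"}
    cols[cb.OUTCOME] = rng.integers(0, 2, size=n)
    cols[cb.INCOME_RAW] = rng.uniform(100, 10_000, size=n)
    cols[cb.PROVINCE] = rng.integers(1, 4, size=n)
    return cols
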