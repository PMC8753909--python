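import warnings

import numpy as np
import pandas as pd
import pytest

from prslife import prs, simulate
from prslife.phecode import default_phecode_map

BASE_SEED = 12345


@pytest.fixture(scope="session")
def panel97():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return prs.default_panel()


@pytest.fixture(scope="session")
def small_panel():
    return prs.VariantPanel(
        pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3", "v4", "v5"],
                "effect_allele": ["A", "C", "G", "T", "A"],
                "other_allele": ["G", "T", "A", "C", "C"],
                "weight": [0.10, 0.30, 0.05, 0.02, 0.07],
                "freq": [0.5, 0.2, 0.8, 0.35, 0.6],
            }
        )
    )


@pytest.fixture(scope="session")
def pmap():
    return default_phecode_map()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small cohort under the main preset (PRS effect + obesity phecode)."""
    config = simulate.main_cohort_config(seed=BASE_SEED, n=3000)
    return simulate.generate_cohort(config)


def rng(offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(BASE_SEED + offset)
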