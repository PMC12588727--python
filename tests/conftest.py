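import numpy as np
import pandas as pd
import pytest

from outbreeding import CohortSpec, TRAIT_NAMES, generate_cohort
from outbreeding.simulate import module_correlation
from outbreeding.traits import HET_CLASSES, PLOIDIES


def small_group_sizes(n: int = 40) -> dict:
    """Equal-size design, much smaller than the study, for fast tests."""
    return {(p, h): n for p in PLOIDIES for h in HET_CLASSES}


def independent_correlations() -> dict:
    """Identity correlation for every group: all traits independent."""
    eye = np.eye(len(TRAIT_NAMES))
    return {(p, h): eye for p in PLOIDIES for h in HET_CLASSES}


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One cohort at the printed study design (1622 plants), shared per session."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture()
def small_cohort() -> pd.DataFrame:
    """A fast 360-plant cohort with independent traits and no effects."""
    spec = CohortSpec(seed=11, group_sizes=small_group_sizes(),
                      correlation=independent_correlations())
    return generate_cohort(spec)


@pytest.fixture()
def two_group_table() -> pd.DataFrame:
    """Minimal hand-checkable table: null values {2, 4}, maximum value {6}."""
    return pd.DataFrame({
        "plant_id": ["a", "b", "c"],
        "population": "pop",
        "ploidy": 2,
        "het_class": ["null", "null", "maximum"],
        "plant_height": [2.0, 4.0, 6.0],
    })
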