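import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ursadiet import condition as bc
from ursadiet.diet import FoodItemTable, classify_years
from ursadiet.simulate import StudyConfig, example_taxonomy, gen_condition, gen_study

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def taxonomy() -> FoodItemTable:
    return FoodItemTable.from_frame(example_taxonomy())


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """One default synthetic study on disk, shared across I/O tests."""
    out = tmp_path_factory.mktemp("study")
    gen_study(StudyConfig(), 7, out)
    return out


def observations_for(seed: int, config: StudyConfig | None = None) -> pd.DataFrame:
    """Generate photos -> session conditions -> observation table."""
    config = config or StudyConfig()
    photos, events, _ = gen_condition(config, seed)
    by_cell: dict = {}
    for p in photos:
        by_cell.setdefault((p.bear_id, p.year, p.session), []).append(p)
    conditions = [c for c in (bc.session_condition(v) for v in by_cell.values())
                  if c is not None]
    classes = classify_years(config.pine_august, config.salmon_september)
    return bc.build_observations(conditions, events, classes)


@pytest.fixture(scope="session")
def default_observations() -> pd.DataFrame:
    return observations_for(1)
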