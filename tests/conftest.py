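import numpy as np
import pandas as pd
import pytest

from napus_phenomics import config as cfgmod
from napus_phenomics import defaults
from napus_phenomics.simulate import (
    GenerativeModel, _assign_seed_diameters, assign_genotypes,
    build_pouch_layout, proportional_panel,
)
from napus_phenomics.types import PouchDesign


@pytest.fixture(scope="session")
def small_cfg() -> dict:
    """Reduced-scale configuration for pipeline-level tests."""
    cfg = cfgmod.load_config()
    cfg["pouch"]["n_runs"] = 2
    cfg["icpms"]["leaf_runs"] = 3
    cfg["icpms"]["leaf_samples"] = 400
    cfg["icpms"]["seed_runs"] = 2
    cfg["icpms"]["seed_samples"] = 300
    return cfg


@pytest.fixture(scope="session")
def recovery_frame() -> pd.DataFrame:
    """5,000 seedling positions over the pouch design with genotypes,
    habits and seed-diameter classes assigned: the shared backbone for
    variance-recovery simulations."""
    layout = build_pouch_layout(PouchDesign(n_runs=7))
    rng = np.random.default_rng(20240901)
    panel = proportional_panel(defaults.GENOTYPES_PER_RUN * 7)
    df = assign_genotypes(layout, panel, rng)
    df["seed_diameter"] = _assign_seed_diameters(df, rng)
    return df.iloc[:5000].reset_index(drop=True)


@pytest.fixture(scope="session")
def quiet_model() -> GenerativeModel:
    """Generator with attrition switched off (clean-data experiments)."""
    return GenerativeModel(attrition_rate=0.0)
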