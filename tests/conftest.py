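import numpy as np
import pandas as pd
import pytest

import cnadose as cd


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return cd.datasets.load_table1()


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return cd.datasets.load_table2()


@pytest.fixture(scope="session")
def set_counts() -> dict:
    return cd.datasets.load_exclusive_set_counts()


@pytest.fixture(scope="session")
def small_config() -> cd.CohortConfig:
    """Desk-scale cohort with a coarse marker grid for fast tests."""
    return cd.CohortConfig(marker_spacing=50_000, n_genes=600)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> cd.Cohort:
    return cd.generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_result(small_cohort) -> cd.pipeline.PipelineResult:
    c = small_cohort
    return cd.analyze_cohort(c.markers, c.tumor_expr, c.control_expr,
                             c.genome, c.clinical,
                             params=cd.PipelineParams(seed=7))
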