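import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from srnaheterosis.io_formats import SampleSheet, TrioCountMatrix
from srnaheterosis.synthetic_data import SimulationConfig, trio_sample_sheet


@pytest.fixture(scope="session")
def trio_sheet() -> SampleSheet:
    return trio_sample_sheet(3)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_features=300, n_regions=90)


@pytest.fixture
def tiny_matrix(trio_sheet) -> TrioCountMatrix:
    """3 features x 9 samples with hand-set counts."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(10, 100, size=(3, 9)),
        index=pd.Index(["fa", "fb", "fc"], name="feature_id"),
        columns=list(trio_sheet.sample_ids),
    )
    return TrioCountMatrix(counts, trio_sheet, "miRNA")
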