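import warnings

import pandas as pd
import pytest

from thermoperf.synth import (
    SynthConfig,
    generate_calibration,
    generate_performance,
    generate_te_series,
    generate_tolerance,
)

# Mixed-model boundary fits legitimately warn; keep test output readable.
warnings.filterwarnings("ignore", message=".*variance component.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def performance(config) -> pd.DataFrame:
    return generate_performance(config)


@pytest.fixture(scope="session")
def tolerance(config) -> pd.DataFrame:
    return generate_tolerance(config)


@pytest.fixture(scope="session")
def te_table(config) -> pd.DataFrame:
    return generate_te_series(config)


@pytest.fixture(scope="session")
def calibration_pairs(config) -> pd.DataFrame:
    return generate_calibration(config)


@pytest.fixture(scope="session")
def te_series(te_table, tmp_path_factory):
    from thermoperf.operative import read_logger_csv

    path = tmp_path_factory.mktemp("te") / "te_series.csv"
    te_table.to_csv(path, index=False)
    return read_logger_csv(path)
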