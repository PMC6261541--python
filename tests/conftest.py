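import numpy as np
import pandas as pd
import pytest

from moodpe.config import PipelineConfig
from moodpe.synthetic_data import SimConfig, simulate
from moodpe import io


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced-dimension study: fast enough for per-test pipeline runs."""
    return SimConfig(n_msas=3, counties_per_msa=3, postal_per_msa=8,
                     gambling_msas=2, teams_per_msa=2, n_days=120, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated study under the default conditions."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_sim):
    """Small simulated study written out as interchange CSVs."""
    tables, truth = small_sim
    d = tmp_path_factory.mktemp("simdata")
    for name, df in tables.items():
        io.write_table(df, d / f"{name}.csv")
    io.write_json(truth, d / "ground_truth.json")
    return d


@pytest.fixture(scope="session")
def pipeline_run(sim_dir, tmp_path_factory):
    from moodpe.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeout")
    cfg = PipelineConfig(data_dir=str(sim_dir), seed=5, n_sims=2000)
    log = run_pipeline(cfg, out)
    return cfg, out, log


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def year_2013() -> pd.DatetimeIndex:
    return pd.date_range("2013-01-01", "2013-12-31", freq="D")
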