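import numpy as np
import pytest

import tdagene as tg


@pytest.fixture(scope="session")
def small_sim():
    """Small planted dataset: 5 TFs, 20 targets, 60 cells, mild noise."""
    cfg = tg.SimConfig(n_tfs=5, n_targets=20, n_cells=60, noise_sd=0.2,
                       dropout_rate=0.1, seed=7)
    expr, network, tfs = tg.simulate_dataset(cfg)
    return cfg, expr, network, tfs


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_sim):
    """The small dataset written out in the BEELINE dialects."""
    _, expr, network, tfs = small_sim
    out = tmp_path_factory.mktemp("fixture")
    paths = tg.write_fixture(network, tfs, expr, out)
    return paths


@pytest.fixture(scope="session")
def default_sim():
    """The study-condition fixture: 10 TFs, 100 targets, 300 cells."""
    cfg = tg.SimConfig(seed=0)
    expr, network, tfs = tg.simulate_dataset(cfg)
    return cfg, expr, network, tfs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
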