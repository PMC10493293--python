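import numpy as np
import pytest

from hrfpipe import BlockParadigm, RunConfig
from hrfpipe.pipeline import simulate


@pytest.fixture(scope="session")
def paradigm():
    """The default 20-block 10 s / 20 s paradigm at TR 1 s."""
    return BlockParadigm()


@pytest.fixture(scope="session")
def short_paradigm():
    """A 4-block paradigm for cheap epoching tests."""
    return BlockParadigm(n_blocks=4)


@pytest.fixture(scope="session")
def noisefree_dataset(tmp_path_factory):
    """Noise-free synthetic dataset with the full default paradigm."""
    td = tmp_path_factory.mktemp("noisefree")
    cfg = RunConfig(data_dir=str(td / "ds"), out_dir=str(td / "out"),
                    dims=(20, 20, 10), n_structures=30,
                    noise_sd=0.0, response_amplitude_sd=0.0,
                    drift_slope=0.0, seed=1)
    dataset = simulate(cfg)
    return cfg, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
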