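import numpy as np
import pytest

from resistscan import poolseq, simulate, sweep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sweep_dataset():
    """One synthetic three-population scan with a sweep at sdhB."""
    gen = np.random.default_rng(2024)
    return simulate.simulate_scan_dataset(gen)


@pytest.fixture(scope="session")
def sweep_windows(sweep_dataset):
    return poolseq.window_stats(
        sweep_dataset.sites,
        poolseq.SubsampleConfig(b=50, assume_full_coverage=True),
        pools=sweep_dataset.pools,
        seed=7,
    )


@pytest.fixture(scope="session")
def sweep_called(sweep_windows):
    scan = sweep.pbe_scan(sweep_windows, "RES1", ("SUS1", "SUS2"))
    return sweep.call_outliers(scan, quantile=0.01)
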