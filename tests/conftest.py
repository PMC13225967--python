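import numpy as np
import pytest

from thzash import optics, synth


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """Six-sample deterministic cohort: no noise, scatter or thickness error."""
    cfg = synth.CohortConfig.noiseless(n_samples=6, seed=11)
    table, traces, ref = synth.generate_cohort(cfg)
    return cfg, table, traces, ref


@pytest.fixture(scope="session")
def small_noiseless_datasets(small_noiseless_cohort):
    cfg, table, traces, ref = small_noiseless_cohort
    return cfg, table, optics.build_datasets(traces, ref, table)


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-sized cohort (183 samples, 3 replicates, default noise)."""
    cfg = synth.CohortConfig(seed=7)
    table, traces, ref = synth.generate_cohort(cfg)
    return cfg, table, traces, ref


@pytest.fixture(scope="session")
def default_datasets(default_cohort):
    cfg, table, traces, ref = default_cohort
    return cfg, table, optics.build_datasets(traces, ref, table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
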