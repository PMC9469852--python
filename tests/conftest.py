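import numpy as np
import pandas as pd
import pytest

import famequant as fq


@pytest.fixture(scope="session")
def wild_true():
    return fq.preset_profile("wild")


@pytest.fixture(scope="session")
def wild_cfg():
    return fq.preset_config("wild")


@pytest.fixture(scope="session")
def noiseless():
    return fq.NoiseModel(cv=0.0, fish_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def wild_peaks_noiseless(wild_true, wild_cfg, noiseless):
    """One noiseless whole-lipid replicate of the wild preset."""
    return fq.simulate_peaks(wild_true, wild_cfg, noiseless, n_fish=1, n_replicates=1, group="wild")


@pytest.fixture(scope="session")
def wild_fraction_peaks_noiseless(wild_true, noiseless):
    cfg = fq.preset_config("wild", fractions=True)
    return fq.simulate_fraction_run(wild_true, cfg, noiseless, n_fish=2, n_replicates=2, group="wild")
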