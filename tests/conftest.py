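import numpy as np
import pandas as pd
import pytest

from endosource import simulate as sim


@pytest.fixture(scope="session")
def pool314():
    return sim.make_taxon_pool(314, rng_seed=1)


@pytest.fixture()
def noiseless_params():
    return sim.AssemblyParams(detection_prob=1.0, false_peak_rate=0.0, rng_seed=1)


@pytest.fixture()
def noiseless_exp(noiseless_params, pool314):
    return sim.simulate_experiment(noiseless_params, pool314)


def make_peaks(rows):
    """Build a raw peak DataFrame from (sample, bio, tech, dye, size, height) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "bio_rep", "tech_rep", "dye", "size_bp", "height"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
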