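import warnings

import numpy as np
import pandas as pd
import pytest

from ecotyping import synthetic
from ecotyping.containers import CellFractions


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_truth():
    """Small planted world: 3 cell types, K = 2/3/3, 3 communities."""
    return synthetic.generate_truth(
        450,
        ["A", "B", "C"],
        {"A": 2, "B": 3, "C": 3},
        n_markers_per_state=30,
        effect_size_log2=2.0,
        n_communities=3,
        community_noise_rate=0.1,
        n_samples=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """Noisy bulk cohort + true signature + estimated fractions."""
    from ecotyping import deconvolution

    bulk = synthetic.simulate_bulk(small_truth, noise_sd_log2=0.5, seed=7)
    sig = synthetic.true_signature(small_truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fr = deconvolution.estimate_fractions(bulk, sig)
    return bulk, sig, fr


@pytest.fixture(scope="session")
def noiseless_cohort(small_truth):
    bulk = synthetic.simulate_bulk(small_truth, noise_sd_log2=0.0, seed=7)
    return bulk, CellFractions(small_truth.fractions)


def survival_frame(time, event, **cols):
    n = len(time)
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id")
    return pd.DataFrame({"time": time, "event": event, **cols}, index=idx)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
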