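import dataclasses

import numpy as np
import pandas as pd
import pytest

from predatt import paradigm, synthetic
from predatt.montage import reduced_montage


@pytest.fixture(scope="session")
def small_montage():
    return reduced_montage()


@pytest.fixture(scope="session")
def noise_free_config(small_montage):
    """Deterministic study conditions: no noise, no between-subject variance."""
    cfg = synthetic.default_effect_config(
        n_subjects_per_group=1, n_blocks=2, montage=small_montage,
        noise_sd=0.0, rng_seed=0)
    return dataclasses.replace(cfg, subject_amp_sd=0.0, subject_rt_sd_ms=0.0)


@pytest.fixture(scope="session")
def two_block_session():
    return paradigm.generate_session(2, seed=7)


@pytest.fixture(scope="session")
def noise_free_subject(noise_free_config, two_block_session):
    epochs, presses = synthetic.simulate_subject(
        noise_free_config, "18-24", two_block_session, seed=11)
    return epochs, presses


def make_events(categories, soa_ms=paradigm.SOA_MS, block=0):
    """Hand-built event table for scoring/selection tests."""
    return pd.DataFrame({
        "onset_ms": np.arange(len(categories)) * soa_ms,
        "category": pd.Categorical(list(categories),
                                   categories=paradigm.CATEGORIES),
        "block": block,
        "position": np.arange(len(categories)),
    })


def make_presses(times_ms, block=0):
    return pd.DataFrame({"press_time_ms": list(times_ms),
                         "block": [block] * len(times_ms)})
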