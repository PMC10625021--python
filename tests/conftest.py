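import numpy as np
import pandas as pd
import pytest

from trajcluster import encoding, medoids, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort (n=400, seed 7)."""
    cfg = simulate.GeneratorConfig(n_patients=400, rng_seed=7)
    events, covariates, truth = simulate.generate_cohort(cfg)
    return cfg, events, covariates, truth


@pytest.fixture(scope="session")
def small_sequences(small_cohort):
    _, events, _, truth = small_cohort
    ids, seqs = encoding.encode_cohort(events, truth["patient_id"].tolist())
    return ids, seqs


@pytest.fixture(scope="session")
def small_medoids(small_sequences):
    _, seqs = small_sequences
    return medoids.compress(seqs, k=30, rng_seed=0)


def make_events(rows):
    """rows: iterable of (patient_id, event_type, start_day, end_day)."""
    return pd.DataFrame(rows, columns=list(simulate.EVENT_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
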