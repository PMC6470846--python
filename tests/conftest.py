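import numpy as np
import pytest

from fallkit import AccelRecording, SliceFeaturizer, simulate_study

TRAIN_SEEDS = (101, 102, 103)
TEST_SEED = 201


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_recording():
    """Ten minutes of a motionless, worn sensor (gravity along z)."""
    n = 10 * 6000
    return AccelRecording(ax=np.zeros(n), ay=np.zeros(n), az=np.ones(n),
                          temperature=np.full(n, 31.0))


@pytest.fixture(scope="session")
def study():
    """Fitted featurizer + train/test tables of the default simulated study.

    Three 120-minute training recordings with 18 falls each, one held-out
    120-minute recording with 10 falls, all fully worn.
    """
    train_recs = [simulate_study(duration_min=120, n_falls=18, seed=s)[0]
                  for s in TRAIN_SEEDS]
    test_rec, test_specs = simulate_study(duration_min=120, n_falls=10,
                                          seed=TEST_SEED)
    featurizer = SliceFeaturizer().fit(train_recs)
    train_table = featurizer.transform(train_recs)
    test_table = featurizer.transform(test_rec)
    return {"featurizer": featurizer, "train": train_table,
            "test": test_table, "test_rec": test_rec,
            "test_specs": test_specs}
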