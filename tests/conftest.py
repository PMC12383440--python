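import numpy as np
import pytest

from modfuse import harness, phantom, preprocess


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def cohort10(small_spec):
    return phantom.generate_cohort(small_spec, 10)


@pytest.fixture(scope="session")
def desk_cfg():
    return harness.desk_config(task_seed=0, epochs=5)


@pytest.fixture(scope="session")
def wt_dataset(cohort10, desk_cfg):
    return preprocess.build_slice_dataset(cohort10, "WT", desk_cfg.preprocess)


@pytest.fixture(scope="session")
def trained_wt(cohort10, desk_cfg, wt_dataset):
    """One desk-scale trained model on a subject-level holdout split; shared by
    every test that needs a trained network.  Slices thinned to every other z
    to keep the run short."""
    thinned = [r for r in wt_dataset if r.z_index % 2 == 0]
    train_ids, test_ids = harness.holdout_split(
        [s.subject_id for s in cohort10], 0.3, desk_cfg.seed)
    train_recs = [r for r in thinned if r.subject_id in train_ids]
    test_recs = [r for r in thinned if r.subject_id in test_ids]
    result = harness.train(train_recs, desk_cfg)
    return result, train_recs, test_recs


def random_mask_pair(rng: np.random.Generator, shape=(16, 16), p=0.3):
    """Pair of random binary masks used by metric-oracle tests."""
    return (rng.uniform(size=shape) < p).astype(np.uint8), \
           (rng.uniform(size=shape) < p).astype(np.uint8)
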