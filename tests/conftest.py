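import numpy as np
import pytest

import pathcare as pc


@pytest.fixture
def toy_schema():
    return pc.FeatureSchema(("hr", "sbp", "lactate"))


@pytest.fixture
def toy_cohort(toy_schema):
    """Two hand-built patients with irregular missingness."""
    nan = np.nan
    p1 = pc.VisitSequence(
        "a", np.array([[70.0, 120.0, nan],
                       [nan, 118.0, 2.0],
                       [75.0, nan, nan]]),
        np.array([[True, True, False],
                  [False, True, True],
                  [True, False, False]]),
        {"mortality": 0})
    p2 = pc.VisitSequence(
        "b", np.array([[nan, 130.0, 1.0],
                       [80.0, nan, nan],
                       [82.0, 140.0, 3.0]]),
        np.array([[False, True, True],
                  [True, False, False],
                  [True, True, True]]),
        {"mortality": 1})
    return pc.Cohort(toy_schema, [p1, p2], {"a": "train", "b": "train"})


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort with its ground truth."""
    return pc.generate_cohort(pc.SynthConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    cohort, _truth = small_cohort
    processed, stats = pc.preprocess(cohort)
    return processed, stats


@pytest.fixture(scope="session")
def small_batch(small_processed):
    processed, _ = small_processed
    return next(pc.batch_cohort(processed, "train", 48))
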