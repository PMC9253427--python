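import numpy as np
import pytest
from hypothesis import settings

from discount_design import (
    ChoiceDataset,
    ChoiceRecord,
    ModelParams,
    Trial,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(records, subject_id="s0", condition="reward", run="A"):
    return ChoiceDataset(subject_id, condition, run, records)


def record(condition, r1, r2, delay, action, rt_ms=None, target_p1=None):
    return ChoiceRecord(Trial(condition, r1, r2, delay, target_p1=target_p1),
                        action, rt_ms)


@pytest.fixture
def hyperbolic_params():
    return ModelParams("hyperbolic", kappa=0.1, beta=1.0)


@pytest.fixture
def reward_records():
    """Mixed immediate/delayed reward choices on a small grid."""
    rng = np.random.default_rng(42)
    recs = []
    for D in (2, 7, 30, 90, 180):
        for r2 in (2.0, 5.0, 10.0, 20.0):
            r1 = round(float(rng.uniform(0.2, 0.9) * r2), 2)
            action = "immediate" if rng.uniform() < 0.5 else "delayed"
            recs.append(record("reward", r1, r2, D, action))
    return recs


@pytest.fixture
def reward_dataset(reward_records):
    return make_dataset(reward_records)
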