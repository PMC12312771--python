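import numpy as np
import pytest

from ipdmasem.generate import ConditionSpec
from ipdmasem.runner import run_condition
from ipdmasem._oracles import make_toy_dataset


@pytest.fixture(scope="session")
def toy_ds():
    return make_toy_dataset(seed=3)


@pytest.fixture(scope="session")
def toy_ds_missing():
    return make_toy_dataset(seed=3, missing=True)


@pytest.fixture(scope="session")
def np_s3_k50_records():
    """300 replications of naive pooling under the high-ICC unequal scenario,
    k=50, complete data: the condition where ignoring clustering is most
    pathological. Shared by the SE-bias and exact-fit acceptance checks."""
    cond = ConditionSpec("S3_high_unequal", k=50, missing=False, master_seed=2026)
    return run_condition(cond, methods=("NP",), reps=300)


@pytest.fixture(scope="session")
def model_based_s3_k50_records():
    """200 replications of the model-based estimators (partially saturated,
    two-level, one-stage MASEM) on the same high-ICC scenario; model-true
    fits, so exact fit should reject at ~alpha and close fit ~never."""
    cond = ConditionSpec("S3_high_unequal", k=50, missing=False, master_seed=2026)
    return run_condition(
        cond, methods=("PS", "2L", "OSMASEM"), reps=200, compute_se=False
    )
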