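import numpy as np
import pytest
from hypothesis import settings

from treeallom import AgeGroup, TreeRecord, default_config, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(
    w=(1.0, 1.0, 1.0, 1.0),
    D=10.0,
    H=12.0,
    CR=3.0,
    group=AgeGroup.MIDDLE,
    tree_id="t1",
):
    return TreeRecord(
        tree_id=tree_id,
        D=D,
        H=H,
        CR=CR,
        w_trunk=w[0],
        w_branch=w[1],
        w_leaf=w[2],
        w_root=w[3],
        group=group,
    )


@pytest.fixture(scope="session")
def default_records():
    """The default 72-tree synthetic inventory (18/19/35 per age group)."""
    return simulate_dataset(default_config(seed=0))


@pytest.fixture(scope="session")
def large_young_records():
    """A large single-group sample for Monte-Carlo checks."""
    cfg = default_config(seed=7, n_per_group={AgeGroup.YOUNG: 5000,
                                              AgeGroup.MIDDLE: 2,
                                              AgeGroup.MATURE: 2})
    recs = simulate_dataset(cfg)
    return [r for r in recs if r.group is AgeGroup.YOUNG]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
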