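import numpy as np
import pytest

import midti
from midti.data_io import build_dataset
from midti.training import fuse_problem, problem_from_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fixture_bundle():
    """Easy synthetic instance with its fused networks and CV dataset,
    shared across tests (fusion is deterministic for the fixed seed)."""
    data, config = midti.easy_fixture(seed=1)
    problem = problem_from_synthetic(data)
    fused_d, fused_t = fuse_problem(problem, config)
    dataset = build_dataset(problem.dti, ratio=config.ratio, seed=config.seed)
    return {
        "data": data,
        "config": config,
        "problem": problem,
        "fused_d": fused_d,
        "fused_t": fused_t,
        "dataset": dataset,
    }


@pytest.fixture(scope="session")
def tiny_problem():
    """A very small instance for structural and harness tests."""
    spec = midti.SyntheticSpec(n_drugs=12, n_targets=15, k_d=2, k_t=2,
                               n_diseases=20, n_side_effects=15,
                               assoc_density=0.1, noise=0.0, seed=3)
    data = midti.generate(spec)
    return problem_from_synthetic(data)
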