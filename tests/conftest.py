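import numpy as np
import pytest

import caremcda as cm


@pytest.fixture(scope="session")
def core_set():
    return cm.build_core_set()


@pytest.fixture(scope="session")
def example_perf():
    """Worked-example two-programme performance table (SE = 0)."""
    return cm.example_performance_table()


@pytest.fixture(scope="session")
def example_w():
    """The two hypothetical stakeholder-group weight vectors (P1, P2)."""
    return cm.example_weights()


@pytest.fixture(scope="session")
def truth():
    return cm.default_truth(seed=0)


@pytest.fixture(scope="session")
def small_design(truth):
    """A small optimized design (3 sub-designs x 6 sets) for fast DCE tests."""
    return cm.optimize_design(truth.part_worths, n_subdesigns=3, n_sets=6, seed=0)
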