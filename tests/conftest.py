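import numpy as np
import pytest

import egalnet as eg


@pytest.fixture(scope="session")
def treatments():
    """The five standard 25-node treatments on one fixed draw."""
    return eg.standard_treatments(25, 10, 200, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def never_give():
    """Saturated-low probability intercept: nobody ever gives."""
    return eg.BehaviorParams(a_p=-20.0, c_x=0, c_r=0, c_l=0, c_k=0)


@pytest.fixture(scope="session")
def always_give():
    """Saturated-high probability intercept: everyone with tokens gives."""
    return eg.BehaviorParams(a_p=20.0, c_x=0, c_r=0, c_l=0, c_k=0)


@pytest.fixture(scope="session")
def small_experiment():
    """Two synthetic sessions of 18 subjects with subject heterogeneity."""
    spec = eg.SessionSpec(n_subjects=18, sigma_subj=0.3)
    records, logs = eg.generate_sessions(2, spec, seed=42)
    return records, logs
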