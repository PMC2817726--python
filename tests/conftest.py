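import numpy as np
import pytest
from hypothesis import settings

from strokemeta import GenotypeStudy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20100209)


@pytest.fixture
def basic_study():
    return GenotypeStudy(
        study_id="s1",
        polymorphism_id="rsX",
        disease="ischemic stroke",
        year=2001,
        case_counts=(10, 20, 70),
        control_counts=(5, 15, 80),
    )


def random_effect_sets(rng, n_sets, k_range=(3, 12)):
    """Random (values, ses) fixtures for oracle-equivalence checks."""
    out = []
    for _ in range(n_sets):
        k = int(rng.integers(*k_range, endpoint=True))
        ys = rng.normal(0.2, 0.4, k)
        ses = rng.uniform(0.05, 0.6, k)
        out.append((ys.tolist(), ses.tolist()))
    return out
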