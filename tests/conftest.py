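import numpy as np
import pytest

from wase.simulate import SessionConfig, simulate_cohort


@pytest.fixture(scope="session")
def low_intensity_cohort():
    """Small low-intensity cohort: scores spread across bands, two-class labels."""
    cfg = SessionConfig.low_intensity().replace(n_athletes=8, n_steps=150)
    ds = simulate_cohort(cfg)
    assert len(np.unique(ds.labels)) == 2, "fixture must have both label classes"
    return ds


@pytest.fixture(scope="session")
def tiny_default_cohort():
    """Tiny cohort under the faithful default generator conditions."""
    return simulate_cohort(SessionConfig(n_athletes=4, n_steps=50))
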