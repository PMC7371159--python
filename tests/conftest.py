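import numpy as np
import pytest

import sibvar as sv


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale study-mimic cohort (~100 children), fixed seed."""
    cfg = sv.scale_composition(sv.study_mimic_config(seed=424242), 0.15)
    return sv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def mimic_cohort():
    """Full-scale study-mimic cohort (711 children), fixed seed."""
    return sv.generate_cohort(sv.study_mimic_config(seed=20200720))


def ln_outcome(cohort):
    return np.log(cohort.table["bmi"].to_numpy(float))
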