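import numpy as np
import pytest

import connmanova as cm


@pytest.fixture(scope="session")
def paper_cohort() -> cm.CohortTable:
    """Study-sized synthetic cohort (N=193) drawn once per session."""
    return cm.generate_cohort(cm.default_paper_spec(), seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-dimension dataset (N=100, p=30) with a planted interaction."""
    spec = cm.scaled_down_spec(delta=1.0)
    cohort, panels = cm.generate_dataset(spec, seed=7)
    return spec, cohort, panels


@pytest.fixture(scope="session")
def null_dataset():
    """Reduced-dimension fully-null dataset (delta=0, zero confound effects)."""
    spec = cm.scaled_down_spec(delta=0.0, null_confounds=True)
    cohort, panels = cm.generate_dataset(spec, seed=13)
    return spec, cohort, panels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def factorial_design(rng: np.random.Generator, n: int) -> cm.DesignMatrix:
    """Random full-cell 2x2 factorial design for array-level tests."""
    while True:
        sex = rng.choice([1.0, -1.0], n)
        dx = rng.choice([1.0, -1.0], n)
        if len({(s, d) for s, d in zip(sex, dx)}) == 4:
            break
    X = np.column_stack([np.ones(n), sex, dx, sex * dx])
    return cm.DesignMatrix(X)
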