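import numpy as np
import pytest

from inlimbo.pipeline import TWO_REGION_ANALYSIS, analyze_subject
from inlimbo.simulate import two_region_spec, generate_subject, task_design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def canonical_subject():
    """One canonical synthetic subject: BOLD, truth masks, design, spec."""
    spec = two_region_spec(seed=7)
    bold, truth = generate_subject(spec, 0)
    return spec, bold, truth, task_design(spec)


@pytest.fixture(scope="session")
def canonical_result(canonical_subject):
    """Full single-subject pipeline result on the canonical subject."""
    spec, bold, truth, design = canonical_subject
    mask = np.ones(spec.grid, dtype=bool)
    res = analyze_subject(bold, mask, design, [1.0, 0.0], seed=7,
                          **TWO_REGION_ANALYSIS)
    return spec, truth, res
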