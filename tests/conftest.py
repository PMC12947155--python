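import numpy as np
import pytest

from synecv import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """Default 108-patient synthetic cohort."""
    return generate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def big_cohort(spec):
    """Large cohort at the default sex ratio, for calibration checks."""
    return generate_cohort(spec, seed=42, n_male=6944, n_female=3056)


@pytest.fixture(scope="session")
def noise_free_spec(spec):
    """The default spec with every residual SD set to zero."""
    from dataclasses import replace

    return replace(spec, subgroups=tuple(replace(g, eps_sd=0.0) for g in spec.subgroups))


@pytest.fixture(scope="session")
def homogeneous_spec(spec):
    """Single true line for both sexes and all BMI (no interaction, no break)."""
    from dataclasses import replace

    groups = []
    for g in spec.subgroups:
        groups.append(
            replace(g, slope=0.864, intercept=-2.09, hu_mean=49.0, hu_sd=4.0, eps_sd=3.4)
        )
    return replace(spec, subgroups=tuple(groups))
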