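import numpy as np
import pytest

from skelphen import synthetic as syn

STANDARDS = [("polyester", 400.0), ("aluminum", 1800.0)]


@pytest.fixture
def noiseless_params():
    return syn.CurveParams(
        stiffness=100.0, yield_load=10.0, max_load=15.0,
        fracture_fraction=0.8, hardening_ratio=0.1, noise_sd=0.0,
    )


@pytest.fixture
def noisy_params(noiseless_params):
    from dataclasses import replace

    return replace(noiseless_params, noise_sd=0.05)


@pytest.fixture
def cohort_model():
    return syn.default_cohort_model(n=320, seed=11)


@pytest.fixture
def reference_cohort(cohort_model):
    return syn.gen_reference_cohort(cohort_model)


@pytest.fixture
def gray_field():
    return syn.gen_gray_field(
        bone_density_mean=1200.0, bone_density_sd=100.0,
        standards=STANDARDS, size=(96, 96), seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
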