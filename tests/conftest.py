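import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pkval import (
    DEFAULT_DISPOSITION,
    NOISE_FREE,
    DispositionParams,
    SamplingSchedule,
    apply_assay,
    simulate_profile,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def mono_params():
    """Mono-exponential disposition 100·e^(−0.2 t), dose 5000 µg/kg."""
    return DispositionParams(terms=((100.0, 0.2),), dose=5000.0)


@pytest.fixture
def tri_params():
    return DEFAULT_DISPOSITION


@pytest.fixture
def paper_schedule():
    return SamplingSchedule()


@pytest.fixture
def noise_free_profile(tri_params, paper_schedule):
    """Deterministic tri-exponential profile at the 12-point study schedule."""
    return apply_assay(simulate_profile(tri_params, paper_schedule, NOISE_FREE))


@pytest.fixture
def dense_mono_profile(mono_params):
    """Mono-exponential sampled densely from 0 to 60 h (NCA closed forms)."""
    from pkval import ConcentrationTimeProfile, model_concentration

    t = np.linspace(0.0, 60.0, 601)
    return ConcentrationTimeProfile(
        subject_id="dense",
        dose=mono_params.dose,
        times=t,
        concentrations=model_concentration(mono_params, t),
    )
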