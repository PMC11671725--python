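import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from n2opart.iso_core import Process, ProcessSignature, SourceLibrary
from n2opart.partition_ls import EmittedMeasurement
from n2opart.synthetic_data import GroundTruth, forward_measurement

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library() -> SourceLibrary:
    """The shipped literature source library."""
    return SourceLibrary.default()


@pytest.fixture(scope="session")
def exact_library() -> SourceLibrary:
    """Library with all SDs collapsed to zero (deterministic sources)."""
    sigs = tuple(
        ProcessSignature(s.process, s.sp_mean, 0.0, s.o18_mean, 0.0)
        for s in SourceLibrary.default().signatures
    )
    return SourceLibrary(signatures=sigs, eps_sp_sd=0.0, eps_o_sd=0.0)


@pytest.fixture(scope="session")
def study_truth() -> GroundTruth:
    """Default (study-condition) ground truth of the forward simulator."""
    return GroundTruth()


@pytest.fixture(scope="session")
def study_measurement(study_truth) -> EmittedMeasurement:
    """Noise-free emitted measurement forward-generated at the study truth."""
    return forward_measurement(study_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240926)


def random_simplex(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Uniform draws on the 4-simplex (Dirichlet(1,1,1,1))."""
    return rng.dirichlet(np.ones(4), size=n)
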