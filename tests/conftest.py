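import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from cbctqa import reference, run_dose_stage, run_iq_stage  # noqa: E402


@pytest.fixture(scope="session")
def ref_readouts():
    return reference.reference_tld_readouts()


@pytest.fixture(scope="session")
def ref_weighting():
    return reference.reference_weighting()


@pytest.fixture(scope="session")
def ref_voi_stats():
    return reference.reference_voi_stats()


@pytest.fixture(scope="session")
def dose_result(ref_readouts, ref_weighting):
    return run_dose_stage(ref_readouts, ref_weighting)


@pytest.fixture(scope="session")
def iq_result(ref_voi_stats):
    return run_iq_stage(ref_voi_stats)
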