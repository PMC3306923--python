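import pytest
from hypothesis import HealthCheck, settings

import spkdose as s

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Default kinetic parameters (16 h elimination half-life)."""
    return s.PKParameters()


@pytest.fixture(scope="session")
def tables():
    return s.ReferenceTables.default()


@pytest.fixture(scope="session")
def study_doses():
    """Packaged per-subject PBPK and SPK I/II/III dose table."""
    return s.load_study_doses()


@pytest.fixture
def complete_record():
    """A fully measured input record (no defaults needed)."""
    return s.InputRecord(
        subject_id="114",
        period=s.Season.SUMMER,
        agricultural=True,
        route_code=int(s.Slot.FIRST_MORNING),
        uer_avg=0.02,
        body_weight=17.0,
        exposure_start=19.0,
        t_p=21.0,
        t_c=31.0,
        concentration=1.0,
        volume=0.2,
    )
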