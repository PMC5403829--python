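import numpy as np
import pytest

from sleepacuity import actigraphy, cohort, ump


@pytest.fixture
def ref_params() -> ump.UMPParams:
    """A plausible parameter vector used across model tests."""
    return ump.UMPParams(
        v=65.0, beta=10.0, tau=24.0, phi=5.0, alpha=-1.0,
        S0_init=4.0, U=10.0, L0_init=6.0,
    )


def make_week_timeline(n_days: int = 7, bedtime: float = 23.5, duration: float = 7.3):
    """n_days nightly sleep events inside a study span starting at midnight."""
    events = []
    for d in range(n_days):
        start = d * 24.0 + bedtime
        events.append(
            actigraphy.SleepEvent(
                start=np.datetime64("2017-01-02") + np.timedelta64(int(start * 60), "m"),
                end=np.datetime64("2017-01-02") + np.timedelta64(int((start + duration) * 60), "m"),
                minutes_asleep=int(duration * 60) - 10,
                minutes_restless=10,
            )
        )
    span_end = np.datetime64("2017-01-02") + np.timedelta64(int((n_days * 24 + 8) * 60), "m")
    return actigraphy.build_timeline(events, (np.datetime64("2017-01-02"), span_end))


@pytest.fixture
def week_timeline():
    return make_week_timeline()


@pytest.fixture
def clean_device() -> cohort.DeviceModel:
    """A device that reports RTs without frame quantization or latency."""
    return cohort.DeviceModel("lab", 1.0, 0.0, None)


@pytest.fixture
def clean_participant(ref_params, clean_device) -> cohort.TrueParticipant:
    return cohort.TrueParticipant("T01", ref_params, clean_device)


@pytest.fixture
def clean_spec() -> cohort.CohortSpec:
    """Noise-free, training-free, quantization-free generator settings."""
    return cohort.CohortSpec(
        noise_sd=0.0,
        training_amplitude=0.0,
        questions_per_assessment=40,
        pvt_misfire_rate=0.0,
        fragmentation_rate=0.0,
        hr_dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort() -> cohort.CohortData:
    """Two-participant fully compliant cohort shared by read-only tests."""
    spec = cohort.CohortSpec(n_participants=2, seed=42, fragmentation_rate=0.0)
    return cohort.generate_cohort(spec)
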