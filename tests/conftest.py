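import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from csdwave.core import ProbeGeometry, Session, assign_layers

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def probe() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture
def layers(probe):
    return assign_layers(probe)


def make_session(
    signal: np.ndarray,
    sample_rate: float,
    kcl_time: float = 0.0,
    stim_times=(),
    probe: ProbeGeometry | None = None,
    boundaries=(600.0, 1000.0),
) -> Session:
    """Wrap a raw signal matrix into a Session for unit tests."""
    signal = np.asarray(signal)
    if probe is None:
        probe = ProbeGeometry(n_sites=signal.shape[0]) \
            if signal.shape[0] >= 3 else ProbeGeometry()
    return Session(
        signal=signal,
        sample_rate=sample_rate,
        probe=probe,
        layers=assign_layers(probe, boundaries),
        stim_times=np.asarray(stim_times, dtype=float),
        kcl_time=kcl_time,
        duration=signal.shape[1] / sample_rate,
    )
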