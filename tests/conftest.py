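import dataclasses

import numpy as np
import pytest

from vmrpipe import (
    DistentionProtocol,
    EMGTrace,
    RecordingSession,
    SessionMeta,
    default_effects,
)

SHORT_PROTOCOL = DistentionProtocol(inflation_onset=90.0, pre_period=90.0)


@pytest.fixture(scope="session")
def effects_cfg():
    """The packaged effect configuration (study percentages, default noise)."""
    return default_effects()


@pytest.fixture(scope="session")
def noise_free_cfg(effects_cfg):
    """Packaged configuration with rat and session variability removed."""
    return dataclasses.replace(effects_cfg, rat_cv=0.0, session_cv=0.0)


@pytest.fixture
def short_protocol():
    return dataclasses.replace(SHORT_PROTOCOL)


def make_step_session(
    multiple: float,
    baseline_uv: float = 2.0,
    sampling_rate: float = 100.0,
    protocol: DistentionProtocol | None = None,
    step_volume: float = 0.5,
    meta: SessionMeta | None = None,
) -> RecordingSession:
    """Deterministic session: constant |EMG|, stepping to ``multiple``x at a
    given distention volume.  Used as the analytic ground truth for the
    criterion mechanics."""
    protocol = protocol or dataclasses.replace(SHORT_PROTOCOL)
    duration = protocol.inflation_onset + protocol.ramp_duration + 10.0
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    step_time = protocol.inflation_onset + step_volume / (protocol.infusion_rate / 60.0)
    samples = np.where(t < step_time, baseline_uv, baseline_uv * multiple)
    meta = meta or SessionMeta(rat_id="step", group="shamENDO", stage="P")
    return RecordingSession(
        meta=meta,
        emg=EMGTrace(samples, sampling_rate=sampling_rate),
        protocol=protocol,
    )
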