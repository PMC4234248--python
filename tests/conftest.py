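import numpy as np
import pytest

import fcqual as fq


def tone(freq_hz, duration_s=0.5, fs=fq.WORKING_RATE_HZ, amp=0.3):
    t = np.arange(int(round(duration_s * fs))) / fs
    return fq.AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t), fs)


@pytest.fixture(scope="session")
def speechlike():
    """A 1 s female-like fixture at 65 dB SPL presentation level."""
    return fq.make_speechlike(fq.TALKER_PRESETS["f1"]).at_level(65.0)


@pytest.fixture(scope="session")
def short_speechlike():
    """A 0.5 s fixture for the cheaper end-to-end checks."""
    from dataclasses import replace

    spec = replace(fq.TALKER_PRESETS["m1"], duration_s=0.5)
    return fq.make_speechlike(spec).at_level(65.0)


@pytest.fixture(scope="session")
def condition_set(speechlike):
    return fq.make_condition_set(speechlike)
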