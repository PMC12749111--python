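"""Shared fixtures: channels, trace builders, and small synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from mepkit.core import AveragedTrace, MuscleChannel, StimSetting
from mepkit.simulate import default_channels

FS = 22000.0
EPOCH_SAMPLES = 2200  # 100 ms at 22 kHz / 10 Hz stimulation


@pytest.fixture
def facial_channel() -> MuscleChannel:
    return MuscleChannel(
        label="CL_Nasalis", group="facial", laterality="CL",
        detection_window_ms=(5.0, 18.0),
    )


@pytest.fixture
def limb_channel() -> MuscleChannel:
    return MuscleChannel(
        label="CL_ECR", group="limb", laterality="CL",
        detection_window_ms=(16.5, 30.5),
    )


@pytest.fixture
def channels() -> list[MuscleChannel]:
    return default_channels()


@pytest.fixture
def make_trace(facial_channel):
    """Build an AveragedTrace from raw values (default: facial, 22 kHz)."""

    def _make(values, channel=None, fs=FS, n_pulses=120):
        return AveragedTrace(
            values=np.asarray(values, dtype=float),
            fs_hz=fs,
            channel=channel if channel is not None else facial_channel,
            n_pulses_averaged=n_pulses,
        )

    return _make


@pytest.fixture
def times_ms():
    return np.arange(EPOCH_SAMPLES) * 1000.0 / FS


def gaussian_bump(times_ms: np.ndarray, center_ms: float, fwhm_ms: float, amp: float) -> np.ndarray:
    sigma = fwhm_ms / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((times_ms - center_ms) / sigma) ** 2)


@pytest.fixture
def setting() -> StimSetting:
    return StimSetting(amplitude_mA=3.0, setting_id="S0")
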