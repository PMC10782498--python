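import logging

import numpy as np
import pytest

from samc.detect import SpindleEvent
from samc.sde import PowerTrace
from samc.synthgen import SynthSpec, generate

logging.getLogger("samc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def short_synth():
    """A 2-minute default-condition recording with ground truth."""
    rec, anns = generate(SynthSpec(duration_s=120.0, seed=7))
    return rec, anns


def make_trace(norm, fs=100.0, peak_freq=13.0, channel="C3", keep=None):
    """PowerTrace from a raw norm_power array (constant peak frequency)."""
    norm = np.asarray(norm, dtype=float)
    if keep is None:
        keep = np.ones(len(norm), dtype=bool)
    return PowerTrace(norm_power=norm, peak_freq=np.full(len(norm), peak_freq),
                      fs=fs, keep_mask=np.asarray(keep, dtype=bool), channel=channel)


def make_event(onset, offset, channels=("C3",), peak=0.9, freq=13.0, p2p=30.0):
    return SpindleEvent(onset_s=onset, offset_s=offset, channels=frozenset(channels),
                        peak_norm_power=peak, peak_freq_hz=freq,
                        area=0.5 * (offset - onset), p2p_amp_uv=p2p,
                        cls="slow" if freq < 13 else "fast")
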