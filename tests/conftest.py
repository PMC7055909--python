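import dataclasses

import numpy as np
import pytest

from nsavoice import synthesize_waveform
from nsavoice.synth import PROFILES


def clean_profile(name: str, f0_hz: float = 220.0, **overrides):
    """A deterministic, perturbation-free variant of a preset profile."""
    base = dict(jitter_pct=0.0, shimmer_pct=0.0, noise_snr_db=float("inf"), f0_hz=f0_hz)
    base.update(overrides)
    return dataclasses.replace(PROFILES[name], **base)


@pytest.fixture(scope="session")
def modal_record():
    """2 s modal token at 44.1 kHz with 0.5 s silence pads, default perturbations."""
    return synthesize_waveform(PROFILES["modal"], 2.0, silence_s=0.5, seed=101)


@pytest.fixture(scope="session")
def clean_modal_record():
    """Noiseless, perturbation-free 220 Hz modal token, no silence."""
    return synthesize_waveform(clean_profile("modal"), 2.0, silence_s=0.0, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
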