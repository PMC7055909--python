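"""WAV and ground-truth-sidecar I/O.

Audio travels as mono 16-bit PCM WAV; each synthetic record may carry a
JSON sidecar (same stem, ``.json``) with its generation ground truth so
that downstream stages can be scored against it.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .synth import VoiceTypeProfile, WaveformRecord, WaveformTruth

__all__ = ["read_wav", "write_wav", "write_sidecar", "read_sidecar", "load_record"]

_INT_SCALES = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path) -> WaveformRecord:
    """Read a PCM WAV into a record with samples in [-1, 1].

    Multi-channel files are reduced to their first channel with a warning.
    """
    try:
        with warnings.catch_warnings():
            # a premature EOF means a corrupt file, not a usable one
            warnings.simplefilter("error", wavfile.WavFileWarning)
            rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted errors on bad headers
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        warnings.warn(f"{path}: {data.shape[1]}-channel file; using first channel")
        data = data[:, 0]
    dtype = data.dtype
    if dtype in _INT_SCALES:
        samples = data.astype(float) / _INT_SCALES[dtype]
    elif dtype == np.dtype("uint8"):
        samples = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(dtype, np.floating):
        samples = data.astype(float)
    else:
        raise ValueError(f"unsupported WAV sample format {dtype}")
    return WaveformRecord(samples=samples, rate_hz=float(rate))


def write_wav(path, rec: WaveformRecord) -> None:
    """Write a record as mono 16-bit PCM, peak-safe."""
    x = np.round(np.clip(rec.samples, -1.0, 1.0) * 32768.0)
    wavfile.write(
        path, int(round(rec.rate_hz)), np.clip(x, -32768, 32767).astype(np.int16)
    )


def write_sidecar(path, rec: WaveformRecord) -> None:
    if rec.truth is None:
        raise ValueError("record has no ground truth to write")
    t = rec.truth
    prof = t.profile
    payload = {
        "profile": {
            "name": prof.name,
            "harmonic_weights": list(prof.harmonic_weights),
            "jitter_pct": prof.jitter_pct,
            "shimmer_pct": prof.shimmer_pct,
            "noise_snr_db": None if math.isinf(prof.noise_snr_db) else prof.noise_snr_db,
            "f0_hz": prof.f0_hz,
        },
        "f0_hz": t.f0_hz,
        "cycle_start_idx": t.cycle_start_idx.tolist(),
        "cycle_periods_s": t.cycle_periods_s.tolist(),
        "cycle_peak_amps": t.cycle_peak_amps.tolist(),
        "voiced_start_idx": t.voiced_start_idx,
        "voiced_end_idx": t.voiced_end_idx,
    }
    Path(path).write_text(json.dumps(payload))


def read_sidecar(path) -> WaveformTruth:
    payload = json.loads(Path(path).read_text())
    p = payload["profile"]
    profile = VoiceTypeProfile(
        name=p["name"],
        harmonic_weights=tuple(p["harmonic_weights"]),
        jitter_pct=p["jitter_pct"],
        shimmer_pct=p["shimmer_pct"],
        noise_snr_db=math.inf if p["noise_snr_db"] is None else p["noise_snr_db"],
        f0_hz=p["f0_hz"],
    )
    return WaveformTruth(
        profile=profile,
        f0_hz=payload["f0_hz"],
        cycle_start_idx=np.asarray(payload["cycle_start_idx"], dtype=int),
        cycle_periods_s=np.asarray(payload["cycle_periods_s"], dtype=float),
        cycle_peak_amps=np.asarray(payload["cycle_peak_amps"], dtype=float),
        voiced_start_idx=payload["voiced_start_idx"],
        voiced_end_idx=payload["voiced_end_idx"],
    )


def load_record(wav_path) -> WaveformRecord:
    """Read a WAV and attach its ground-truth sidecar when present."""
    rec = read_wav(wav_path)
    sidecar = Path(wav_path).with_suffix(".json")
    if sidecar.exists():
        rec.truth = read_sidecar(sidecar)
    return rec
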