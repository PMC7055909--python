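"""Vocal activity detection by short-time energy and zero-crossing rate.

The recording protocol captures one sustained vowel per token with some
leading/trailing silence; feature extraction operates on the voiced
utterance only. Frames are scored by mean-squared energy and by
zero-crossing rate (crossings per second); a frame is voiced when its
energy clears a threshold derived from the noise floor *and* its ZCR stays
below a ceiling (broadband silence dither has near-Nyquist ZCR and is
rejected by the second gate). The longest contiguous voiced run is taken
as the utterance — one utterance per file by design.

The energy threshold is ``min(energy_factor * floor, 0.05 * peak)`` where
``floor`` is the median of the lowest-decile frame energies. The relative
cap makes the detector idempotent: on a record with no silence at all the
floor is itself voiced-level energy, and the 5%-of-peak cap keeps every
voiced frame above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import WaveformRecord

__all__ = [
    "UtteranceSegment",
    "NoVoicedRegionError",
    "short_time_features",
    "detect_utterance",
]


class NoVoicedRegionError(ValueError):
    """Raised when no contiguous voiced run of sufficient length exists."""


@dataclass(frozen=True)
class UtteranceSegment:
    """A voiced region [start_idx, end_idx) within a parent record."""

    start_idx: int
    end_idx: int
    parent: WaveformRecord

    def __post_init__(self) -> None:
        n = len(self.parent.samples)
        if not 0 <= self.start_idx < self.end_idx <= n:
            raise ValueError(
                f"segment [{self.start_idx}, {self.end_idx}) outside record of length {n}"
            )

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start_idx : self.end_idx]

    @property
    def rate_hz(self) -> float:
        return self.parent.rate_hz

    @property
    def start_s(self) -> float:
        return self.start_idx / self.parent.rate_hz

    @property
    def end_s(self) -> float:
        return self.end_idx / self.parent.rate_hz

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.parent.rate_hz


def short_time_features(
    rec: WaveformRecord, frame_s: float = 0.025, hop_s: float = 0.010
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (start sample, energy, zero-crossing rate) series.

    Energy is the mean squared sample in the frame; ZCR is the number of
    sign changes divided by the frame duration, i.e. crossings per second.
    Frames advance by ``hop_s``; the last partial frame is dropped.
    """
    if not 0 < hop_s <= frame_s:
        raise ValueError("need 0 < hop_s <= frame_s")
    x = rec.samples
    frame_len = int(round(frame_s * rec.rate_hz))
    hop_len = int(round(hop_s * rec.rate_hz))
    if frame_len > len(x):
        raise ValueError("frame longer than the signal")
    n_frames = 1 + (len(x) - frame_len) // hop_len
    starts = np.arange(n_frames) * hop_len
    idx = starts[:, None] + np.arange(frame_len)[None, :]
    frames = x[idx]
    energy = np.mean(frames**2, axis=1)
    signs = np.signbit(frames)
    zcr = np.count_nonzero(signs[:, 1:] != signs[:, :-1], axis=1) / frame_s
    return starts, energy, zcr


def detect_utterance(
    rec: WaveformRecord,
    energy_factor: float = 10.0,
    zcr_ceiling: float | None = None,
    min_voiced_s: float = 0.3,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
) -> UtteranceSegment:
    """Locate the single voiced utterance in a record.

    Returns the longest contiguous run of frames that pass both the energy
    and ZCR gates, converted to sample indices. ``zcr_ceiling=None`` uses
    ``rate_hz / 3`` crossings per second: broadband dither crosses at about
    half the sampling rate regardless of rate, while even strongly noisy
    voiced frames stay below a third of it, so the default scales with the
    recording rate. Raises :class:`NoVoicedRegionError` if no run lasts at
    least ``min_voiced_s``.
    """
    if zcr_ceiling is None:
        zcr_ceiling = rec.rate_hz / 3.0
    starts, energy, zcr = short_time_features(rec, frame_s=frame_s, hop_s=hop_s)
    n_frames = len(starts)
    n_floor = max(1, n_frames // 10)
    floor = float(np.median(np.sort(energy)[:n_floor]))
    peak = float(energy.max())
    threshold = min(energy_factor * floor, 0.05 * peak)
    voiced = (energy > threshold) & (zcr < zcr_ceiling)

    # longest contiguous run of voiced frames
    best_start, best_len = -1, 0
    run_start, run_len = -1, 0
    for i, v in enumerate(voiced):
        if v:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    frame_len = int(round(frame_s * rec.rate_hz))
    hop_len = int(round(hop_s * rec.rate_hz))
    if best_len == 0:
        raise NoVoicedRegionError("vad: no voiced region found")
    run_dur = ((best_len - 1) * hop_len + frame_len) / rec.rate_hz
    if run_dur < min_voiced_s:
        raise NoVoicedRegionError(
            f"vad: longest voiced run {run_dur:.3f} s < min_voiced_s {min_voiced_s:.3f} s"
        )
    start_idx = int(starts[best_start])
    last = best_start + best_len - 1
    if last == n_frames - 1:
        # run reaches the final frame: extend through the uncovered tail
        end_idx = len(rec.samples)
    else:
        end_idx = int(starts[last]) + frame_len
    return UtteranceSegment(start_idx=start_idx, end_idx=end_idx, parent=rec)
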