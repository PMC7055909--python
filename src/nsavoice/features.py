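"""The seven-dimensional voice-type feature vector [H1,H2,H3,H4,SE,Jr,Sr].

Spectral features come from one Hamming-windowed magnitude spectrum of the
whole amplitude-normalized utterance, zero-padded to a frequency resolution
of at most 1 Hz:

* Harmonic quotients ``H_i = A_i / (A_1 + ... + A_5)``, where ``A_i`` is
  the largest spectral magnitude within ±f0/4 of the i-th harmonic of the
  fundamental. Harmonics above the 1500 Hz analysis band contribute
  ``A_i = 0``. The five quotients sum to one by construction; the first
  four are the features (H5 is linearly redundant).
* Spectral entropy ``SE = −Σ p_i log p_i`` over the normalized power
  spectral density in 0–3000 Hz — small for tonal signals, large for
  noise-like signals. Natural log (nats) by default; the base is
  switchable.

Stability features come from the time-domain cycle series: per-cycle
periods ``T_i`` and peak magnitudes ``A_i`` found by period-synchronous
peak picking with parabolic sub-sample refinement, then

* jitter  ``Jr = mean|T_i − T_{i+1}| / mean(T_i)``
* shimmer ``Sr = mean|A_i − A_{i+1}| / mean(A_i)``

Both are kept as fractions internally; multiply by 100 for percent.
Amplitude normalization of the waveform and of the spectrum removes any
loudness dependence from every feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq, irfft

from .synth import WaveformRecord
from .vad import UtteranceSegment, detect_utterance

__all__ = [
    "SpectrumView",
    "CycleSeries",
    "FeatureVector",
    "UnvoicedError",
    "InsufficientCyclesError",
    "UndefinedFeatureError",
    "FEATURE_NAMES",
    "compute_spectrum",
    "estimate_f0",
    "harmonic_amplitudes",
    "harmonic_quotients",
    "spectral_entropy",
    "detect_cycles",
    "jitter",
    "shimmer",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = ("H1", "H2", "H3", "H4", "SE", "Jr", "Sr")

#: Band searched for harmonics (Hz); the vibration sensor's useful band.
HARMONIC_BAND_HZ: tuple[float, float] = (50.0, 1500.0)
#: Band over which the spectral-entropy density is normalized (Hz).
ENTROPY_BAND_HZ: tuple[float, float] = (0.0, 3000.0)


class UnvoicedError(ValueError):
    """No reliable fundamental in the search band."""


class InsufficientCyclesError(ValueError):
    """Fewer than two valid vocal cycles detected."""


class UndefinedFeatureError(ValueError):
    """A feature's defining ratio has a zero denominator."""


@dataclass(frozen=True)
class SpectrumView:
    """A magnitude spectrum on a uniform frequency grid."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.magnitude):
            raise ValueError("freqs_hz and magnitude must have equal length")
        if np.any(np.asarray(self.magnitude) < 0):
            raise ValueError("magnitudes must be nonnegative")


@dataclass(frozen=True)
class CycleSeries:
    """Per-cycle periods (s) and peak amplitudes of a voiced segment."""

    periods: np.ndarray
    peak_amps: np.ndarray

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.peak_amps):
            raise ValueError("periods and peak_amps must have equal length")
        if len(self.periods) < 2:
            raise InsufficientCyclesError(
                "cycles: need at least 2 cycles for perturbation measures"
            )
        if np.any(np.asarray(self.periods) <= 0):
            raise ValueError("all periods must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.periods)


@dataclass(frozen=True)
class FeatureVector:
    """[H1, H2, H3, H4, SE, Jr, Sr] with an optional voice-type label.

    Quotients are dimensionless in [0, 1] with H1+..+H4 <= 1 (H5 implied);
    SE is entropy in the configured log base (nats by default); Jr and Sr
    are fractions (x100 for percent).
    """

    H1: float
    H2: float
    H3: float
    H4: float
    SE: float
    Jr: float
    Sr: float
    label: str | None = None

    def __post_init__(self) -> None:
        h = (self.H1, self.H2, self.H3, self.H4)
        if any(not 0 <= v <= 1 for v in h) or sum(h) > 1 + 1e-9:
            raise ValueError("harmonic quotients must lie in [0,1] with sum <= 1")
        if self.SE < 0 or self.Jr < 0 or self.Sr < 0:
            raise ValueError("SE, Jr, Sr must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.H1, self.H2, self.H3, self.H4, self.SE, self.Jr, self.Sr])


def _segment_samples(seg: UtteranceSegment | np.ndarray, rate_hz: float | None):
    if isinstance(seg, UtteranceSegment):
        return seg.samples, seg.rate_hz
    if rate_hz is None:
        raise ValueError("rate_hz required when passing a raw sample array")
    return np.asarray(seg, dtype=float), float(rate_hz)


def compute_spectrum(
    seg: UtteranceSegment | np.ndarray,
    rate_hz: float | None = None,
    max_resolution_hz: float = 1.0,
) -> SpectrumView:
    """Hamming-windowed magnitude spectrum of a whole utterance.

    The segment is amplitude-normalized to unit peak before windowing, and
    zero-padded so the bin spacing is at most ``max_resolution_hz``; the
    magnitude is normalized to a maximum of 1.
    """
    x, rate = _segment_samples(seg, rate_hz)
    if len(x) == 0:
        raise ValueError("empty segment")
    peak = float(np.max(np.abs(x)))
    if peak == 0:
        raise ValueError("all-zero segment")
    x = x / peak
    window = np.hamming(len(x))
    nfft = next_fast_len(max(len(x), int(math.ceil(rate / max_resolution_hz))))
    mag = np.abs(rfft(x * window, nfft))
    mag = mag / mag.max()
    return SpectrumView(
        freqs_hz=rfftfreq(nfft, 1.0 / rate), magnitude=mag, resolution_hz=rate / nfft
    )


def estimate_f0(
    seg: UtteranceSegment | np.ndarray,
    rate_hz: float | None = None,
    fmin_hz: float = 70.0,
    fmax_hz: float = 400.0,
    min_corr: float = 0.3,
) -> float:
    """Autocorrelation fundamental-frequency estimate with parabolic
    sub-sample refinement.

    Raises :class:`UnvoicedError` when the normalized autocorrelation peak
    in the lag band is below ``min_corr`` (noise-like signal, or no
    periodicity in the requested band).
    """
    if not 0 < fmin_hz < fmax_hz:
        raise ValueError("need 0 < fmin_hz < fmax_hz")
    x, rate = _segment_samples(seg, rate_hz)
    x = x - x.mean()
    n = len(x)
    lag_min = int(math.floor(rate / fmax_hz))
    lag_max = int(math.ceil(rate / fmin_hz))
    if lag_max >= n or lag_min < 1:
        raise ValueError("segment too short for the requested frequency band")
    nfft = next_fast_len(2 * n)
    spec = rfft(x, nfft)
    r = irfft(spec * np.conj(spec), nfft)[: lag_max + 2]
    if r[0] <= 0:
        raise UnvoicedError("f0: zero-energy segment")
    r = r / r[0]
    band = r[lag_min : lag_max + 1]
    k = int(np.argmax(band)) + lag_min
    if r[k] < min_corr:
        raise UnvoicedError(
            f"f0: autocorrelation peak {r[k]:.2f} < {min_corr} in "
            f"[{fmin_hz:.0f}, {fmax_hz:.0f}] Hz — unvoiced"
        )
    # parabolic refinement around the peak lag
    if 1 <= k < len(r) - 1:
        denom = r[k - 1] - 2 * r[k] + r[k + 1]
        delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return rate / (k + delta)


def harmonic_amplitudes(
    spec: SpectrumView,
    f0_hz: float,
    n_harmonics: int = 5,
    band_hz: tuple[float, float] = HARMONIC_BAND_HZ,
) -> np.ndarray:
    """Amplitudes of the first ``n_harmonics`` harmonics.

    ``A_i`` is the maximum spectral magnitude within ±f0/4 of ``i * f0``;
    harmonics above the band's upper edge contribute 0.
    """
    if f0_hz <= 0:
        raise ValueError("f0_hz must be positive")
    freqs, mag = spec.freqs_hz, spec.magnitude
    amps = np.zeros(n_harmonics)
    for i in range(1, n_harmonics + 1):
        fc = i * f0_hz
        if fc > band_hz[1]:
            continue
        lo, hi = fc - f0_hz / 4.0, fc + f0_hz / 4.0
        sel = (freqs >= lo) & (freqs <= hi)
        if sel.any():
            amps[i - 1] = float(mag[sel].max())
    return amps


def harmonic_quotients(
    spec: SpectrumView,
    f0_hz: float,
    band_hz: tuple[float, float] = HARMONIC_BAND_HZ,
) -> tuple[float, float, float, float]:
    """First four harmonic quotients ``H_i = A_i / (A_1 + ... + A_5)``."""
    amps = harmonic_amplitudes(spec, f0_hz, band_hz=band_hz)
    total = amps.sum()
    if total == 0:
        raise UndefinedFeatureError("harmonics: all-zero spectrum in the search band")
    h = amps / total
    return float(h[0]), float(h[1]), float(h[2]), float(h[3])


def spectral_entropy(
    spec: SpectrumView,
    band_hz: tuple[float, float] = ENTROPY_BAND_HZ,
    base: float | None = None,
) -> float:
    """Shannon entropy of the normalized power spectral density in
    ``band_hz``; ``base=None`` means natural log (nats)."""
    sel = (spec.freqs_hz >= band_hz[0]) & (spec.freqs_hz <= band_hz[1])
    density = spec.magnitude[sel] ** 2
    total = density.sum()
    if total == 0:
        raise UndefinedFeatureError("entropy: all-zero spectrum in the band")
    p = density / total
    p = p[p > 0]
    se = float(-np.sum(p * np.log(p))) + 0.0  # normalize -0.0
    if base is not None:
        se /= math.log(base)
    return se


def _refine_peak(x: np.ndarray, k: int) -> tuple[float, float]:
    """Parabolic sub-sample refinement of a local maximum at index k."""
    if k <= 0 or k >= len(x) - 1:
        return float(k), float(x[k])
    xm, x0, xp = x[k - 1], x[k], x[k + 1]
    denom = xm - 2 * x0 + xp
    if denom == 0:
        return float(k), float(x0)
    delta = 0.5 * (xm - xp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = x0 - 0.25 * (xm - xp) * delta
    return k + delta, float(value)


def detect_cycles(
    seg: UtteranceSegment | np.ndarray,
    f0_hz: float,
    rate_hz: float | None = None,
) -> CycleSeries:
    """Period-synchronous peak picking on a voiced segment.

    One maximal positive peak is found per window of width ~1/f0, each
    window advanced peak-to-peak; peak positions and heights are refined
    by parabolic interpolation. Peaks below 10% of the median peak height
    are rejected (they are residual silence, not glottal pulses — VAD
    boundaries are frame-quantized and may leak a few milliseconds of
    near-silence into the segment). Cycle i runs from valid peak i to the
    *adjacent* valid peak i+1: ``T_i`` is the inter-peak interval, ``A_i``
    the height of peak i. Cycles with ``T_i`` outside [0.5, 2]/f0 are
    discarded.
    """
    if f0_hz <= 0:
        raise ValueError("f0_hz must be positive")
    x, rate = _segment_samples(seg, rate_hz)
    period = rate / f0_hz
    n = len(x)
    if n < int(1.5 * period):
        raise InsufficientCyclesError("cycles: segment shorter than 1.5 periods")

    peaks = []
    first_win = x[: int(1.5 * period)]
    p = int(np.argmax(first_win))
    peaks.append(p)
    while True:
        lo = int(round(p + 0.5 * period))
        hi = int(round(p + 1.5 * period))
        if lo >= n - 1:
            break
        hi = min(hi, n)
        q = lo + int(np.argmax(x[lo:hi]))
        peaks.append(q)
        p = q

    pos, amp = [], []
    for k in peaks:
        pk, vk = _refine_peak(x, k)
        pos.append(pk)
        amp.append(vk)
    pos = np.asarray(pos)
    amp = np.asarray(amp)

    valid_peak = amp >= 0.1 * np.median(amp)
    periods = np.diff(pos) / rate
    amps = amp[:-1]
    valid = valid_peak[:-1] & valid_peak[1:]
    valid &= (periods >= 0.5 / f0_hz) & (periods <= 2.0 / f0_hz)
    periods, amps = periods[valid], amps[valid]
    if len(periods) < 2:
        raise InsufficientCyclesError(
            f"cycles: only {len(periods)} valid cycles detected"
        )
    return CycleSeries(periods=periods, peak_amps=amps)


def jitter(cycles: CycleSeries) -> float:
    """Relative frequency perturbation:
    ``Jr = mean|T_i − T_{i+1}| / mean(T_i)`` (a fraction)."""
    t = np.asarray(cycles.periods, dtype=float)
    return float(np.mean(np.abs(np.diff(t))) / np.mean(t))


def shimmer(cycles: CycleSeries) -> float:
    """Relative amplitude perturbation:
    ``Sr = mean|A_i − A_{i+1}| / mean(A_i)`` (a fraction)."""
    a = np.asarray(cycles.peak_amps, dtype=float)
    mean_a = np.mean(a)
    if mean_a == 0:
        raise UndefinedFeatureError("shimmer: zero mean amplitude")
    return float(np.mean(np.abs(np.diff(a))) / mean_a)


def extract_features(
    rec: WaveformRecord,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    energy_factor: float = 10.0,
    zcr_ceiling: float | None = None,
    min_voiced_s: float = 0.3,
    fmin_hz: float = 70.0,
    fmax_hz: float = 400.0,
    harmonic_band_hz: tuple[float, float] = HARMONIC_BAND_HZ,
    entropy_band_hz: tuple[float, float] = ENTROPY_BAND_HZ,
    entropy_base: float | None = None,
) -> FeatureVector:
    """Full feature extraction for one record: VAD → spectrum → f0 →
    quotients/entropy, plus cycle detection → jitter/shimmer.

    Deterministic for fixed input; stage errors propagate with their stage
    named in the message. The label is taken from the record's ground
    truth when present.
    """
    seg = detect_utterance(
        rec,
        energy_factor=energy_factor,
        zcr_ceiling=zcr_ceiling,
        min_voiced_s=min_voiced_s,
        frame_s=frame_s,
        hop_s=hop_s,
    )
    f0 = estimate_f0(seg, fmin_hz=fmin_hz, fmax_hz=fmax_hz)
    spec = compute_spectrum(seg)
    h1, h2, h3, h4 = harmonic_quotients(spec, f0, band_hz=harmonic_band_hz)
    se = spectral_entropy(spec, band_hz=entropy_band_hz, base=entropy_base)
    cycles = detect_cycles(seg, f0)
    jr = jitter(cycles)
    sr = shimmer(cycles)
    label = rec.truth.profile.name if rec.truth is not None else None
    return FeatureVector(H1=h1, H2=h2, H3=h3, H4=h4, SE=se, Jr=jr, Sr=sr, label=label)
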