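"""Synthetic neck-surface vibration signals and simulated rating panels.

No recordings of the original sustained-vowel corpus are publicly
deposited, so every downstream stage of this package is exercised on
signals generated here with *known* ground truth. The generative model is
deliberately simple — it is a signal model, not a physiological one:

* A voiced token is a quasi-periodic stack of the first five harmonics of a
  fundamental ``f0``. Per-type spectral envelopes follow the field's
  qualitative picture of phonation on the vocal-fold contact continuum:
  breathy voice concentrates energy in H1, pressed voice shows a prominent
  H2, and modal voice decays monotonically from H1 to H4.
* Cycle-to-cycle frequency perturbation (jitter) and amplitude perturbation
  (shimmer) are injected as i.i.d. Gaussian multiplicative noise on the
  per-cycle period and peak amplitude, rescaled in closed form so the
  relative-perturbation statistics evaluated on the stored per-cycle series
  equal the requested targets exactly.
* Broadband Gaussian noise is added at a controlled harmonic-to-noise power
  ratio; it is the knob that drives spectral entropy.
* Optional leading/trailing "silence" carries a tiny dither (−80 dB re the
  voiced peak) so that frame statistics such as the zero-crossing rate
  remain defined there.

Simulated rater panels draw each rater's category through a per-rater
confusion matrix over {modal, breathy, pressed, none} and a per-rater Beta
confidence distribution, with optional hidden duplicate presentations for
the intra-rater design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .screening import CATEGORIES, VOICE_TYPES, RatingTable

__all__ = [
    "VoiceTypeProfile",
    "WaveformTruth",
    "WaveformRecord",
    "PanelSpec",
    "PROFILES",
    "COHORT_GEOMETRY",
    "synthesize_waveform",
    "sample_profile",
    "simulate_panel",
    "make_feature_cohort",
]

#: Dither level in "silence", relative to the voiced-peak amplitude.
SILENCE_DITHER_DB = -80.0


@dataclass(frozen=True)
class VoiceTypeProfile:
    """Generation targets for one phonation type.

    ``harmonic_weights`` are the relative amplitudes of harmonics 1..5
    before normalization; ``jitter_pct`` and ``shimmer_pct`` are the target
    relative perturbations in percent; ``noise_snr_db`` is the harmonic-to-
    broadband-noise power ratio (``inf`` = noiseless); ``f0_hz=None`` draws
    the fundamental uniformly from 180–250 Hz per record (adult female
    range — the study protocol constrained neither pitch nor loudness).
    """

    name: str
    harmonic_weights: tuple[float, float, float, float, float]
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    noise_snr_db: float = math.inf
    f0_hz: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.harmonic_weights, dtype=float)
        if w.shape != (5,):
            raise ValueError("harmonic_weights must have exactly 5 entries")
        if (w < 0).any() or not np.isfinite(w).all() or w.sum() == 0:
            raise ValueError("harmonic_weights must be nonnegative and not all zero")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter_pct and shimmer_pct must be >= 0")
        if self.f0_hz is not None and not self.f0_hz > 0:
            raise ValueError("f0_hz must be positive")
        object.__setattr__(self, "harmonic_weights", tuple(float(x) for x in w))


#: Default per-type profiles. Envelope shapes follow the qualitative
#: spectral picture (breathy: H1 over 60% of the first-five-harmonic
#: amplitude sum; pressed: prominent H2; modal: monotone decay); the
#: pressed profile carries the lowest harmonic-to-noise ratio so that its
#: spectral entropy is the largest of the three types, and modal voice has
#: the smallest shimmer.
PROFILES: dict[str, VoiceTypeProfile] = {
    "modal": VoiceTypeProfile(
        "modal", (3.0, 1.9, 1.15, 0.7, 0.45), jitter_pct=0.6, shimmer_pct=2.0, noise_snr_db=30.0
    ),
    "breathy": VoiceTypeProfile(
        "breathy", (6.5, 2.0, 1.0, 0.6, 0.4), jitter_pct=0.8, shimmer_pct=6.0, noise_snr_db=25.0
    ),
    "pressed": VoiceTypeProfile(
        "pressed", (2.0, 3.2, 1.6, 0.95, 0.6), jitter_pct=0.7, shimmer_pct=5.0, noise_snr_db=12.0
    ),
}


def sample_profile(
    base: VoiceTypeProfile,
    rng: np.random.Generator,
    weight_log_sd: float = 0.35,
    perturb_log_sd: float = 0.35,
    snr_sd_db: float = 4.0,
) -> VoiceTypeProfile:
    """Draw one token's profile around a per-type template.

    Emulates between-speaker and between-token variability (the study pools
    many speakers who each mimic the target phonation imperfectly):
    harmonic weights and perturbation targets are scattered log-normally,
    the harmonic-to-noise ratio normally. Without this scatter the per-type
    feature distributions are nearly point masses and every classifier is
    perfect — unlike real cohorts, whose feature ranges overlap.
    """
    w = np.asarray(base.harmonic_weights) * rng.lognormal(0.0, weight_log_sd, 5)
    if math.isfinite(base.noise_snr_db):
        # floor at 8 dB: a contact sensor is noise-robust, and noisier
        # tokens would not have survived recording quality control
        snr = max(base.noise_snr_db + rng.normal(0.0, snr_sd_db), 8.0)
    else:
        snr = base.noise_snr_db
    return replace(
        base,
        harmonic_weights=tuple(w),
        jitter_pct=base.jitter_pct * rng.lognormal(0.0, perturb_log_sd),
        shimmer_pct=base.shimmer_pct * rng.lognormal(0.0, perturb_log_sd),
        noise_snr_db=snr,
    )


@dataclass(frozen=True)
class WaveformTruth:
    """Exact generation bookkeeping attached to a synthetic record."""

    profile: VoiceTypeProfile
    f0_hz: float
    cycle_start_idx: np.ndarray  # sample index of each cycle's peak/start
    cycle_periods_s: np.ndarray  # realized per-cycle periods (seconds)
    cycle_peak_amps: np.ndarray  # realized per-cycle peak amplitudes
    voiced_start_idx: int
    voiced_end_idx: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.cycle_start_idx)
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")


@dataclass
class WaveformRecord:
    """A sampled vibration signal plus optional ground truth."""

    samples: np.ndarray
    rate_hz: float
    truth: WaveformTruth | None = None

    def __post_init__(self) -> None:
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.truth is not None and len(self.truth.cycle_start_idx):
            idx = self.truth.cycle_start_idx
            if idx[0] < 0 or idx[-1] >= len(self.samples):
                raise ValueError("truth cycle boundaries outside signal bounds")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


def _calibrated_factors(rng: np.random.Generator, n: int, target: float) -> np.ndarray:
    """Multiplicative factors 1 + c*eps whose relative-perturbation
    statistic mean|x_i - x_{i+1}| / mean(x) equals ``target`` exactly.

    With eps ~ N(0,1) i.i.d., the statistic of 1 + c*eps is
    c*D / (1 + c*ebar) where D = mean|Δeps| and ebar = mean(eps), so
    c = target / (D - target*ebar) solves it in closed form.
    """
    if target == 0:
        return np.ones(n)
    if not 0 < target < 0.5:
        raise ValueError("perturbation target must be a fraction in (0, 0.5)")
    for _ in range(64):
        eps = rng.standard_normal(n)
        d = float(np.mean(np.abs(np.diff(eps))))
        ebar = float(eps.mean())
        denom = d - target * ebar
        if denom <= 0:
            continue
        c = target / denom
        factors = 1.0 + c * eps
        if factors.min() > 0.25:
            return factors
    raise RuntimeError("could not calibrate perturbation factors")


def synthesize_waveform(
    profile: VoiceTypeProfile,
    duration_s: float = 2.0,
    rate_hz: float = 44100.0,
    silence_s: float = 0.0,
    seed: int | None = None,
    randomize_phase: bool = False,
) -> WaveformRecord:
    """Generate one sustained-vowel-like vibration token.

    The waveform is a train of harmonic-stack pulses: peak k+1 follows
    peak k after period ``T_k = (1/f0)(1 + c*eps_k)`` and carries peak
    amplitude ``A_k``, with both perturbation series calibrated so that
    the jitter/shimmer statistics evaluated on the stored truth equal
    ``profile.jitter_pct`` / ``profile.shimmer_pct`` exactly. Each sample
    is rendered from its *nearest* peak — the local shape period is the
    enclosing inter-peak gap and the amplitude is that of the nearest
    peak — so every peak is a smooth interior maximum whose height equals
    its stored truth amplitude (the tiny amplitude step this leaves at
    each mid-gap point is far from all peaks). Broadband Gaussian noise is
    added at ``profile.noise_snr_db``; ``silence_s`` of −80 dB dither is
    pre- and appended. ``truth`` carries the exact peak positions
    ("cycle boundaries"), inter-peak periods and peak amplitudes.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if silence_s < 0:
        raise ValueError("silence_s must be >= 0")
    rng = np.random.default_rng(seed)
    f0 = profile.f0_hz if profile.f0_hz is not None else float(rng.uniform(180.0, 250.0))
    if f0 >= rate_hz / 10.0:
        raise ValueError(
            f"f0={f0:.1f} Hz too high for rate {rate_hz:.0f} Hz: "
            "the fifth harmonic would alias"
        )

    n_cycles = int(math.ceil(duration_s * f0)) + 2
    periods = (1.0 / f0) * _calibrated_factors(rng, n_cycles, profile.jitter_pct / 100.0)
    amps = _calibrated_factors(rng, n_cycles, profile.shimmer_pct / 100.0)
    # peak k sits at peaks[k]; gap k between peaks k and k+1 has length periods[k]
    peaks_t = 0.55 * periods[0] + np.concatenate([[0.0], np.cumsum(periods)])
    peak_amps = np.append(amps, amps[-1])  # one amplitude per peak

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    gap = np.clip(np.searchsorted(peaks_t, t, side="right") - 1, 0, n_cycles - 1)
    left, right = peaks_t[gap], peaks_t[gap + 1]
    use_right = (t - left) > (right - t)
    nearest_peak = np.where(use_right, right, left)
    phase = (t - nearest_peak) / periods[gap]
    ampl = np.where(use_right, peak_amps[gap + 1], peak_amps[gap])

    w = np.asarray(profile.harmonic_weights, dtype=float)
    w = w / w.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, 5) if randomize_phase else np.zeros(5)
    g = np.zeros(n)
    for i in range(5):
        g += w[i] * np.cos(2.0 * np.pi * (i + 1) * phase + phases[i])
    x = ampl * g

    if np.isfinite(profile.noise_snr_db):
        p_harm = float(np.mean(x**2))
        sigma = math.sqrt(p_harm / 10.0 ** (profile.noise_snr_db / 10.0))
        x = x + rng.normal(0.0, sigma, n)

    m = int(round(silence_s * rate_hz))
    if m > 0:
        dither = 10.0 ** (SILENCE_DITHER_DB / 20.0) * max(float(np.max(np.abs(x))), 1e-12)
        lead = rng.normal(0.0, dither, m)
        trail = rng.normal(0.0, dither, m)
        samples = np.concatenate([lead, x, trail])
    else:
        samples = x

    # truth covers the peaks inside the rendered span; cycle k runs from
    # peak k to peak k+1 with period periods[k] and peak amplitude amps[k]
    keep = np.round(peaks_t[:n_cycles] * rate_hz).astype(int) < n
    truth = WaveformTruth(
        profile=profile,
        f0_hz=f0,
        cycle_start_idx=np.round(peaks_t[:n_cycles][keep] * rate_hz).astype(int) + m,
        cycle_periods_s=periods[keep],
        cycle_peak_amps=amps[keep],
        voiced_start_idx=m,
        voiced_end_idx=m + n,
    )
    return WaveformRecord(samples=samples, rate_hz=rate_hz, truth=truth)


# ---------------------------------------------------------------------------
# Simulated rating panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSpec:
    """Configuration of a simulated perceptual rating panel.

    ``rater_confusion`` is either one 4x4 row-stochastic matrix shared by
    all raters or an (n_raters, 4, 4) stack, rows/columns ordered as
    :data:`~nsavoice.screening.CATEGORIES`; ``None`` means identity
    (error-free raters). ``confidence_beta`` gives per-rater (a, b) Beta
    parameters (one pair, shared, or a sequence of pairs).
    ``n_duplicates`` samples are presented a second time to every rater.
    """

    n_raters: int = 5
    rater_confusion: np.ndarray | None = None
    confidence_beta: tuple = (8.0, 1.6)
    n_duplicates: int = 0
    seed: int | None = None

    def confusion_stack(self) -> np.ndarray:
        k = len(CATEGORIES)
        if self.rater_confusion is None:
            mats = np.broadcast_to(np.eye(k), (self.n_raters, k, k)).copy()
        else:
            mats = np.asarray(self.rater_confusion, dtype=float)
            if mats.shape == (k, k):
                mats = np.broadcast_to(mats, (self.n_raters, k, k)).copy()
            if mats.shape != (self.n_raters, k, k):
                raise ValueError(f"rater_confusion must be ({k},{k}) or (n_raters,{k},{k})")
        if (mats < 0).any() or not np.allclose(mats.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("every confusion row must be nonnegative and sum to 1")
        return mats

    def beta_params(self) -> list[tuple[float, float]]:
        cb = np.asarray(self.confidence_beta, dtype=float)
        if cb.shape == (2,):
            return [(float(cb[0]), float(cb[1]))] * self.n_raters
        if cb.shape == (self.n_raters, 2):
            return [(float(a), float(b)) for a, b in cb]
        raise ValueError("confidence_beta must be (a, b) or one pair per rater")


def simulate_panel(truth_labels: list[str], spec: PanelSpec) -> RatingTable:
    """Simulate one balanced rating pass over ``truth_labels``.

    Each rater's category is drawn through their confusion row for the true
    category; confidence is drawn from the rater's Beta distribution.
    The first ``spec.n_duplicates`` samples are rated a second time (ids
    suffixed ``:dup``) with fresh draws, giving the intra-rater design.
    """
    if not truth_labels:
        raise ValueError("truth_labels must be nonempty")
    bad = set(truth_labels) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown truth categories {sorted(bad)}")
    if spec.n_duplicates > len(truth_labels):
        raise ValueError("more duplicates requested than samples")
    mats = spec.confusion_stack()
    betas = spec.beta_params()
    rng = np.random.default_rng(spec.seed)

    width = max(4, len(str(len(truth_labels) - 1)))
    sample_ids = [f"s{i:0{width}d}" for i in range(len(truth_labels))]
    duplicate_map = {sid: f"{sid}:dup" for sid in sample_ids[: spec.n_duplicates]}

    items = list(zip(sample_ids, truth_labels)) + [
        (duplicate_map[sid], truth_labels[i])
        for i, sid in enumerate(sample_ids[: spec.n_duplicates])
    ]
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    rows = []
    for sid, label in items:
        j = cat_idx[label]
        for r in range(spec.n_raters):
            choice = CATEGORIES[rng.choice(len(CATEGORIES), p=mats[r, j])]
            a, b = betas[r]
            conf = float(rng.beta(a, b))
            rows.append((sid, f"r{r}", choice, conf))
    df = pd.DataFrame(rows, columns=["sample_id", "rater_id", "category", "confidence"])
    return RatingTable(ratings=df, duplicate_map=duplicate_map)


# ---------------------------------------------------------------------------
# Feature-space cohort
# ---------------------------------------------------------------------------

#: Per-type feature distributions (mean, sd) for drawing classification
#: cohorts directly in feature space. The geometry mirrors what the
#: waveform-level statistics show for the three phonation types: shimmer
#: (Sr) cleanly separates modal voice (the steadiest loudness), spectral
#: entropy (SE, nats) separates pressed voice, H1 is largest for breathy
#: voice, and jitter (Jr) is identically distributed across types — a
#: deliberately uninformative feature. Harmonic quotients overlap enough
#: that no single H carries a class on its own.
COHORT_GEOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "modal": {
        "H1": (0.42, 0.08), "H2": (0.24, 0.06), "H3": (0.14, 0.05), "H4": (0.09, 0.04),
        "SE": (4.0, 0.4), "Jr": (0.010, 0.003), "Sr": (0.020, 0.008),
    },
    "breathy": {
        "H1": (0.52, 0.08), "H2": (0.20, 0.06), "H3": (0.10, 0.05), "H4": (0.06, 0.04),
        "SE": (4.0, 0.4), "Jr": (0.010, 0.003), "Sr": (0.085, 0.025),
    },
    "pressed": {
        "H1": (0.30, 0.08), "H2": (0.28, 0.06), "H3": (0.15, 0.05), "H4": (0.09, 0.04),
        "SE": (5.0, 0.4), "Jr": (0.010, 0.003), "Sr": (0.035, 0.015),
    },
}


def make_feature_cohort(
    n_per_class: int = 200,
    seed: int | None = None,
    geometry: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Draw a labelled feature table directly from the per-type geometry.

    Returns a DataFrame with columns H1..H4, SE, Jr, Sr and ``label``.
    Values are truncated at small positive floors and the four harmonic
    quotients are rescaled on the rare draws where their sum exceeds 0.98,
    so that an implied fifth quotient remains nonnegative.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    geometry = geometry or COHORT_GEOMETRY
    rng = np.random.default_rng(seed)
    frames = []
    feature_names = ["H1", "H2", "H3", "H4", "SE", "Jr", "Sr"]
    for label, params in geometry.items():
        cols = {}
        for name in feature_names:
            mu, sd = params[name]
            cols[name] = np.maximum(rng.normal(mu, sd, n_per_class), 1e-4)
        h = np.column_stack([cols[f"H{i}"] for i in range(1, 5)])
        hsum = h.sum(axis=1)
        over = hsum > 0.98
        if over.any():
            h[over] *= (0.95 / hsum[over])[:, None]
            for i in range(4):
                cols[f"H{i + 1}"] = h[:, i]
        cols["label"] = np.repeat(label, n_per_class)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
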