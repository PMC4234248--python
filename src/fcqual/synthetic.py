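"""Deterministic synthetic fixtures: vowel-like signals, the eight MUSHRA
processing conditions, and simulated rating tables.

The generator stands in for hearing-aid recordings of natural speech: it
produces harmonic source-filter vowels (impulse train at f0 shaped by formant
resonators), concatenates them with noise bursts under a syllable-rate
amplitude modulation, and processes each talker fixture into the standard
8-condition MUSHRA set (hidden reference, five NFC settings, lowpass anchor,
clip anchor).  Simulated rating tables map true quality scores monotonically
onto the 0-100 MUSHRA scale and add per-subject Gaussian noise.

Two male-like and two female-like talker presets mirror a 2+2 talker design;
all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import AudioSignal, WORKING_RATE_HZ
from .distortions import (
    STANDARD_NFC_CONDITIONS,
    clip_anchor,
    lowpass_anchor,
    nfc_process,
)

__all__ = [
    "FixtureSpec",
    "TALKER_PRESETS",
    "CONDITION_LABELS",
    "make_vowel",
    "make_speechlike",
    "make_condition_set",
    "make_synthetic_ratings",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a vowel-like test signal."""

    f0_hz: float = 120.0
    formant_freqs_hz: tuple = (500.0, 1500.0, 2500.0)
    formant_bandwidths_hz: tuple = (80.0, 120.0, 160.0)
    duration_s: float = 1.0
    syllable_rate_hz: float = 4.0
    noise_floor_db: float = -50.0
    sample_rate_hz: float = WORKING_RATE_HZ
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.formant_freqs_hz)
        if np.any(np.diff(f) <= 0):
            raise ValueError("formants must be ascending")
        if np.any(f >= self.sample_rate_hz / 2):
            raise ValueError("formants must lie below Nyquist")
        if len(self.formant_bandwidths_hz) != f.size:
            raise ValueError("one bandwidth per formant required")


#: Talker presets: two male-like (low f0, formants ~750-3000 Hz) and two
#: female-like (high f0, second/third formants reaching ~1000-4000 Hz), plus
#: mild high-frequency frication content added by make_speechlike.
TALKER_PRESETS: dict[str, FixtureSpec] = {
    "m1": FixtureSpec(f0_hz=115.0, formant_freqs_hz=(600.0, 1200.0, 2400.0),
                      formant_bandwidths_hz=(80.0, 110.0, 160.0), seed=11),
    "m2": FixtureSpec(f0_hz=125.0, formant_freqs_hz=(750.0, 1400.0, 2800.0),
                      formant_bandwidths_hz=(90.0, 120.0, 170.0), seed=12),
    "f1": FixtureSpec(f0_hz=195.0, formant_freqs_hz=(850.0, 2000.0, 3400.0),
                      formant_bandwidths_hz=(90.0, 130.0, 180.0), seed=13),
    "f2": FixtureSpec(f0_hz=215.0, formant_freqs_hz=(1000.0, 2300.0, 3900.0),
                      formant_bandwidths_hz=(100.0, 140.0, 190.0), seed=14),
}

CONDITION_LABELS = (
    "hidden-ref",
    "cr2-fc4k",
    "cr2-fc3k",
    "cr6-fc3k",
    "cr10-fc3k",
    "cr2-fc2k",
    "lowpass",
    "clip",
)


def _resonator_sos(fc: float, bw: float, fs: float) -> np.ndarray:
    """Two-pole formant resonator with unit peak gain."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * fc / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [1.0 - r]
    w, h = sps.freqz(b, a, worN=[fc], fs=fs)
    return np.atleast_2d(np.concatenate([np.asarray(b) / np.abs(h[0]), [0, 0], a]))


def make_vowel(spec: FixtureSpec) -> AudioSignal:
    """Harmonic source at f0 shaped by the formant resonators, plus a weak
    noise floor.  Deterministic for a fixed seed."""
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    # impulse train glottal source
    src = np.zeros(n)
    period = max(1, int(round(fs / spec.f0_hz)))
    src[::period] = 1.0
    y = np.zeros(n)
    for fc, bw in zip(spec.formant_freqs_hz, spec.formant_bandwidths_hz):
        y += sps.sosfilt(_resonator_sos(fc, bw, fs), src)
    peak = np.max(np.abs(y))
    if peak > 0:
        y /= peak
    if np.isfinite(spec.noise_floor_db):
        y += 10.0 ** (spec.noise_floor_db / 20.0) * rng.standard_normal(n)
    return AudioSignal(0.5 * y, fs)


def _fricative_burst(n: int, fs: float, rng, lo=3500.0, hi=9000.0) -> np.ndarray:
    """Bandpassed noise burst emulating frication energy above the formants."""
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def make_speechlike(spec: FixtureSpec) -> AudioSignal:
    """Concatenated vowel segments and fricative noise bursts under a
    syllable-rate amplitude modulation.

    The high-frequency bursts give the NFC processor content above typical
    cutoffs, and the ~4 Hz envelope exercises the modulation stage.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    if n == 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed + 1)

    seg = max(1, int(round(fs / max(spec.syllable_rate_hz, 1e-6) / 2.0)))
    y = np.zeros(n)
    pos = 0
    k = 0
    f = np.asarray(spec.formant_freqs_hz)
    while pos < n:
        m = min(seg, n - pos)
        if k % 2 == 0:
            # vowel segment with slight per-segment formant/f0 variation
            jitter = 1.0 + 0.04 * rng.standard_normal()
            sub = replace(
                spec,
                f0_hz=spec.f0_hz * jitter,
                formant_freqs_hz=tuple(f * (1.0 + 0.03 * rng.standard_normal(f.size))),
                duration_s=m / fs,
                noise_floor_db=-np.inf,
                seed=spec.seed + 100 + k,
            )
            y[pos : pos + m] = make_vowel(sub).samples[:m]
        else:
            y[pos : pos + m] = 0.45 * _fricative_burst(m, fs, rng)
        pos += m
        k += 1

    # raised-cosine syllable-rate envelope
    t = np.arange(n) / fs
    env = 0.55 + 0.45 * np.cos(2.0 * np.pi * spec.syllable_rate_hz * t)
    y *= env
    if np.isfinite(spec.noise_floor_db):
        y += 10.0 ** (spec.noise_floor_db / 20.0) * rng.standard_normal(n)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.5 * y / peak
    return AudioSignal(y, fs)


def make_condition_set(ref: AudioSignal) -> dict[str, AudioSignal]:
    """Process a reference into the 8-condition MUSHRA stimulus set.

    Hidden reference (identity), the five standard NFC settings, the 2 kHz
    Butterworth lowpass anchor, and the 25%-peak clipping anchor.
    """
    out: dict[str, AudioSignal] = {"hidden-ref": ref}
    for label, settings in STANDARD_NFC_CONDITIONS.items():
        out[label] = nfc_process(ref, settings)
    out["lowpass"] = lowpass_anchor(ref)
    out["clip"] = clip_anchor(ref)
    return out


def make_synthetic_ratings(
    true_scores: dict,
    n_subjects: int = 12,
    noise_sd: float = 5.0,
    seed: int = 0,
    group: str = "NH",
) -> pd.DataFrame:
    """Simulate a MUSHRA rating table from true quality scores.

    ``true_scores`` maps (condition, talker) -> score (any bounded scale).
    Scores are mapped by a monotone affine transform onto [5, 95], each
    subject adds i.i.d. Gaussian noise (sd ``noise_sd`` on the 0-100 scale),
    and ratings are clipped to [0, 100].  Deterministic for a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    keys = list(true_scores)
    vals = np.array([true_scores[k] for k in keys], dtype=float)
    lo, hi = vals.min(), vals.max()
    mapped = np.full_like(vals, 50.0) if hi == lo else 5.0 + 90.0 * (vals - lo) / (hi - lo)

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        noise = noise_sd * rng.standard_normal(len(keys))
        for (cond, talker), m, e in zip(keys, mapped, noise):
            rows.append(
                {
                    "subject": f"S{s:02d}",
                    "group": group,
                    "condition": cond,
                    "talker": talker,
                    "rating": float(np.clip(m + e, 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)
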