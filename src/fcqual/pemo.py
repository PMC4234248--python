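"""PEMO auditory front-end with normal-hearing and hearing-impaired variants.

The model computes "internal representations" of sounds: the waveform is
split into auditory channels by a 4th-order gammatone filterbank (one filter
per ERB), each channel is half-wave rectified and lowpass filtered at 1 kHz
(envelope extraction), optionally passed through a hearing-impairment stage
(attenuation + instantaneous expansion driven by an inner/outer hair cell
decomposition of the audiogram), compressed by a cascade of five adaptation
loops, and finally analysed by either an 8 Hz modulation lowpass (``lp``) or
a modulation filterbank (``fb``).

The output is a (time, channel) or (time, channel, modulation band) array in
model units, the comparison domain of the PSM and qc quality measures.

Hearing impairment
------------------
Given an audiogram, thresholds are interpolated to the channel center
frequencies, and the total loss HL in each channel is split into an outer
hair cell part ``OHCL = min(ohc_fraction * HL, ohcl_cap)`` and an inner hair
cell part ``IHCL = HL - OHCL``.  Before adaptation, each channel envelope is
attenuated by IHCL and then expanded sample-by-sample: in the dB domain the
stage's input/output function is the identity above a convergence level
(100 dB full scale), and below it bends downward by up to OHCL with local
slope > 1 — the inverse of the compressive input/output function of the
healthy cochlea, so expansion grows with OHCL and vanishes for OHCL = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal, WORKING_RATE_HZ

__all__ = [
    "FilterbankSpec",
    "Audiogram",
    "ChannelLoss",
    "InternalRepresentation",
    "erb_number",
    "erb_to_hz",
    "design_filterbank",
    "PSM_BANK_EDGES",
    "QC_BANK_EDGES",
    "peripheral_and_envelope",
    "decompose_hearing_loss",
    "hi_stage",
    "adaptation_stage",
    "modulation_stage",
    "compute_internal_representation",
]

#: Peripheral band edges (Hz): the wideband bank used by PSM reaches 15.3 kHz,
#: the telephone-band bank used by qc stops at 4 kHz.
PSM_BANK_EDGES = (235.0, 15_300.0)
QC_BANK_EDGES = (235.0, 4_000.0)

#: Envelope decimation factor applied after the (instantaneous) HI stage and
#: before the adaptation loops; 32 kHz / 8 = 4 kHz comfortably resolves the
#: 5 ms shortest adaptation time constant and the 129 Hz top modulation band.
ENVELOPE_DECIMATION = 8

#: Model amplitude corresponding to the absolute hearing threshold (0 dB SPL
#: under the full-scale-RMS = 100 dB SPL convention).  Also the divisive
#: floor of the adaptation loops.
THRESHOLD_AMPLITUDE = 1e-5

#: Adaptation loop time constants (s), shortest to longest.
ADAPTATION_TAUS = (0.005, 0.05, 0.129, 0.253, 0.5)

#: Overshoot limitation factor of the adaptation cascade.
ADAPTATION_LIMIT = 10.0

#: Modulation filterbank: lowpass cutoff plus bandpass centers (Hz), constant
#: Q = 2, logarithmic spacing up to ~129 Hz.
MODULATION_LOWPASS_HZ = 2.5
MODULATION_CENTERS_HZ = (5.0, 10.0, 16.67, 27.78, 46.3, 77.17, 128.6)


# ---------------------------------------------------------------------------
# ERB scale helpers (Glasberg & Moore)

def erb_number(f_hz):
    """ERB-rate (number of ERBs below ``f_hz``)."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(erb, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


# ---------------------------------------------------------------------------
# Types

@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout: ascending center frequencies (Hz)."""

    center_freqs_hz: np.ndarray
    erb_density: float
    f_lo_hz: float
    f_hi_hz: float

    def __post_init__(self):
        cf = np.atleast_1d(np.asarray(self.center_freqs_hz, dtype=np.float64))
        object.__setattr__(self, "center_freqs_hz", cf)
        if cf.size > 1 and not np.all(np.diff(cf) > 0):
            raise ValueError("center frequencies must be strictly ascending")
        if not self.f_lo_hz <= self.f_hi_hz:
            raise ValueError("f_lo must not exceed f_hi")

    @property
    def n_channels(self) -> int:
        return self.center_freqs_hz.size


@dataclass(frozen=True)
class Audiogram:
    """Pure-tone thresholds: (frequency Hz, threshold dB HL) pairs."""

    freqs_hz: np.ndarray
    thresholds_db_hl: np.ndarray

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.freqs_hz, dtype=np.float64))
        t = np.atleast_1d(np.asarray(self.thresholds_db_hl, dtype=np.float64))
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "thresholds_db_hl", t)
        if f.size != t.size or f.size < 2:
            raise ValueError("audiogram needs >= 2 matching (freq, threshold) pairs")
        if not np.all(np.diff(f) > 0):
            raise ValueError("audiometric frequencies must be ascending")
        if np.any(t < -20) or np.any(t > 120):
            raise ValueError("thresholds must lie within [-20, 120] dB HL")

    @classmethod
    def flat(cls, threshold_db_hl: float, f_lo=125.0, f_hi=16000.0) -> "Audiogram":
        return cls(np.array([f_lo, f_hi]), np.full(2, float(threshold_db_hl)))

    @classmethod
    def from_file(cls, path) -> "Audiogram":
        """Load a two-column delimited text file (Hz, dB HL)."""
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError(f"audiogram file {path!s} must have two columns")
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class ChannelLoss:
    """Total hearing loss of one channel split into IHC and OHC parts."""

    center_freq_hz: float
    total_hl_db: float
    ihcl_db: float
    ohcl_db: float

    def __post_init__(self):
        if abs(self.ihcl_db + self.ohcl_db - self.total_hl_db) > 1e-9:
            raise ValueError("IHCL + OHCL must equal the total loss")
        if self.total_hl_db >= 0 and (self.ihcl_db < 0 or self.ohcl_db < 0):
            raise ValueError("loss components must be nonnegative")


@dataclass(frozen=True)
class InternalRepresentation:
    """Model-unit array indexed (time, channel[, modulation band])."""

    values: np.ndarray
    frame_rate_hz: float
    filterbank: FilterbankSpec
    modulation_mode: str  # "lp" | "fb"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("internal representation must be finite")
        expected_ndim = 2 if self.modulation_mode == "lp" else 3
        if v.ndim != expected_ndim:
            raise ValueError(
                f"mode {self.modulation_mode!r} expects a {expected_ndim}-D array"
            )
        if v.shape[1] != self.filterbank.n_channels:
            raise ValueError("channel axis inconsistent with filterbank")


# ---------------------------------------------------------------------------
# Stages

def design_filterbank(
    sample_rate_hz: float = WORKING_RATE_HZ,
    f_lo_hz: float = PSM_BANK_EDGES[0],
    f_hi_hz: float = PSM_BANK_EDGES[1],
    erb_density: float = 1.0,
) -> FilterbankSpec:
    """Lay out gammatone center frequencies at ``erb_density`` filters per ERB.

    Centers run from ``f_lo_hz`` upward in steps of 1/density ERB; the highest
    center does not exceed ``f_hi_hz``.
    """
    if not 0 < f_lo_hz <= f_hi_hz:
        raise ValueError("band edges must satisfy 0 < f_lo <= f_hi")
    if f_hi_hz > sample_rate_hz / 2:
        raise ValueError(
            f"upper edge {f_hi_hz} Hz above Nyquist {sample_rate_hz / 2} Hz"
        )
    e_lo, e_hi = erb_number(f_lo_hz), erb_number(f_hi_hz)
    n = int(np.floor((e_hi - e_lo) * erb_density + 1e-9)) + 1
    centers = erb_to_hz(e_lo + np.arange(n) / erb_density)
    centers[-1] = min(centers[-1], f_hi_hz)
    return FilterbankSpec(centers, erb_density, f_lo_hz, f_hi_hz)


def peripheral_and_envelope(signal: AudioSignal, fb: FilterbankSpec) -> np.ndarray:
    """Gammatone filtering, half-wave rectification, 1 kHz envelope lowpass.

    Returns a nonnegative (n_samples, n_channels) envelope array at the
    signal's sample rate.
    """
    fs = signal.sample_rate_hz
    x = signal.samples
    env_sos = sps.butter(1, 1000.0, btype="low", fs=fs, output="sos")
    out = np.empty((x.size, fb.n_channels))
    for c, fc in enumerate(fb.center_freqs_hz):
        b, a = sps.gammatone(fc, "iir", fs=fs)
        band = sps.lfilter(b, a, x)
        env = sps.sosfilt(env_sos, np.maximum(band, 0.0))
        out[:, c] = np.maximum(env, 0.0)
    return out


def decompose_hearing_loss(
    ag: Audiogram,
    fb: FilterbankSpec,
    ohc_fraction: float = 0.8,
    ohcl_cap_db: float = 55.0,
) -> list[ChannelLoss]:
    """Interpolate the audiogram to channel centers and split HL into IHCL/OHCL.

    Interpolation is linear in log-frequency vs. dB HL with flat extrapolation
    beyond the outermost audiometric frequencies.  The OHC part is
    ``min(ohc_fraction * HL, ohcl_cap_db)``; the remainder is attributed to
    inner hair cells.
    """
    hl = np.interp(
        np.log10(fb.center_freqs_hz),
        np.log10(ag.freqs_hz),
        ag.thresholds_db_hl,
    )
    hl = np.maximum(hl, 0.0)  # negative (better-than-normal) thresholds: no loss
    losses = []
    for fc, total in zip(fb.center_freqs_hz, hl):
        ohcl = min(ohc_fraction * total, ohcl_cap_db)
        losses.append(ChannelLoss(float(fc), float(total), float(total - ohcl), float(ohcl)))
    return losses


#: dB level (full-scale convention) above which the expansion stage is identity.
EXPANSION_CONVERGENCE_DB = 100.0


def _expand_db(level_db: np.ndarray, ohcl_db: float) -> np.ndarray:
    """Expansive dB-domain I/O curve: out = L - OHCL*((Lc-L)/Lc)^2 below Lc.

    Slope 1 + 2*OHCL*(Lc-L)/Lc^2 >= 1, decreasing toward 1 with level; output
    reduced by exactly OHCL at L = 0 (threshold shift), identity at/above Lc.
    """
    lc = EXPANSION_CONVERGENCE_DB
    deficit = np.maximum(lc - level_db, 0.0) / lc
    return level_db - ohcl_db * deficit**2


def hi_stage(envelopes: np.ndarray, losses: list[ChannelLoss]) -> np.ndarray:
    """Attenuation (IHCL) + instantaneous expansion (OHCL), per channel/sample.

    Channels with zero loss pass through bit-for-bit unchanged, so a zero
    audiogram reproduces the normal-hearing model exactly.
    """
    if envelopes.shape[1] != len(losses):
        raise ValueError("one ChannelLoss per channel required")
    out = envelopes.copy()
    tiny = 1e-30
    for c, loss in enumerate(losses):
        if loss.ihcl_db == 0.0 and loss.ohcl_db == 0.0:
            continue
        e = envelopes[:, c] * 10.0 ** (-loss.ihcl_db / 20.0)
        if loss.ohcl_db > 0.0:
            lvl = EXPANSION_CONVERGENCE_DB + 20.0 * np.log10(np.maximum(e, tiny))
            e = np.where(
                e > tiny,
                10.0 ** ((_expand_db(lvl, loss.ohcl_db) - EXPANSION_CONVERGENCE_DB) / 20.0),
                0.0,
            )
        out[:, c] = e
    return out


def adaptation_stage(
    envelopes: np.ndarray,
    sample_rate_hz: float,
    taus=ADAPTATION_TAUS,
    limit: float = ADAPTATION_LIMIT,
    threshold: float = THRESHOLD_AMPLITUDE,
) -> np.ndarray:
    """Five cascaded divisive feedback (adaptation) loops.

    Each loop divides its input by a lowpass-filtered copy of its own output,
    which maps stationary inputs approximately logarithmically and produces
    overshoot at onsets; overshoots are softly limited to ``limit`` times the
    steady response.  The output is rescaled to model units: 0 for inputs at
    the threshold floor, 100 for a full-scale stationary input.
    """
    if np.any(envelopes < 0):
        raise ValueError("adaptation stage requires nonnegative input")
    x = np.maximum(envelopes, threshold)
    n_t, n_ch = x.shape
    n_loops = len(taus)
    coef = np.array([1.0 / (t * sample_rate_hz) for t in taus])
    # state lower bounds and initialization: steady state for threshold input
    smin = np.array([threshold ** (2.0 ** -(i + 1)) for i in range(n_loops)])
    state = np.tile(smin, (n_ch, 1)).T.copy()  # (loop, channel)

    # Munkner-style soft overshoot limitation parameters per loop
    maxv = (1.0 - smin**2) * limit - 1.0
    factor = maxv * 2.0
    expfac = -2.0 / maxv
    offset = maxv - 1.0

    out = np.empty_like(x)
    for t_i in range(n_t):
        v = x[t_i]
        for i in range(n_loops):
            ratio = v / state[i]
            hot = ratio > 1.0
            if np.any(hot):
                r = ratio[hot]
                ratio[hot] = factor[i] / (1.0 + np.exp(expfac[i] * (r - 1.0))) - offset[i]
            state[i] = np.maximum(state[i] + coef[i] * (ratio - state[i]), smin[i])
            v = ratio
        out[t_i] = v
    base = threshold ** (2.0 ** -n_loops)
    return (out - base) * (100.0 / (1.0 - base))


def _first_order_lowpass_sos(fc_hz: float, fs: float) -> np.ndarray:
    return sps.butter(1, fc_hz, btype="low", fs=fs, output="sos")


def modulation_stage(
    adapted: np.ndarray,
    sample_rate_hz: float,
    mode: str,
    fb: FilterbankSpec,
) -> InternalRepresentation:
    """Modulation analysis of the adapted envelopes.

    ``lp``: first-order 8 Hz lowpass per channel -> (time, channel).
    ``fb``: modulation filterbank per channel (2.5 Hz lowpass + constant-Q
    bandpass bands up to ~129 Hz) -> (time, channel, band).
    """
    if mode == "lp":
        sos = _first_order_lowpass_sos(8.0, sample_rate_hz)
        vals = sps.sosfilt(sos, adapted, axis=0)
        return InternalRepresentation(vals, sample_rate_hz, fb, "lp")
    if mode != "fb":
        raise ValueError("modulation mode must be 'lp' or 'fb'")
    n_bands = 1 + len(MODULATION_CENTERS_HZ)
    vals = np.empty(adapted.shape + (n_bands,))
    sos = _first_order_lowpass_sos(MODULATION_LOWPASS_HZ, sample_rate_hz)
    vals[:, :, 0] = sps.sosfilt(sos, adapted, axis=0)
    for k, fc in enumerate(MODULATION_CENTERS_HZ, start=1):
        bw = fc / 2.0  # constant Q = 2
        sos_bp = sps.butter(
            1,
            [max(fc - bw / 2, 0.1), fc + bw / 2],
            btype="band",
            fs=sample_rate_hz,
            output="sos",
        )
        vals[:, :, k] = sps.sosfilt(sos_bp, adapted, axis=0)
    return InternalRepresentation(vals, sample_rate_hz, fb, "fb")


def compute_internal_representation(
    signal: AudioSignal,
    fb: FilterbankSpec | None = None,
    audiogram: Audiogram | None = None,
    mode: str = "lp",
    ohc_fraction: float = 0.8,
    ohcl_cap_db: float = 55.0,
) -> InternalRepresentation:
    """Full front-end: periphery -> (HI stage) -> adaptation -> modulation.

    Deterministic for a fixed input.  With an all-zero audiogram the output is
    identical to the normal-hearing model.
    """
    if fb is None:
        fb = design_filterbank(signal.sample_rate_hz)
    env = peripheral_and_envelope(signal, fb)
    if audiogram is not None:
        losses = decompose_hearing_loss(audiogram, fb, ohc_fraction, ohcl_cap_db)
        env = hi_stage(env, losses)
    # decimate before the (nonlinear but slow) adaptation loops
    env_rate = signal.sample_rate_hz / ENVELOPE_DECIMATION
    env = np.maximum(sps.resample_poly(env, 1, ENVELOPE_DECIMATION, axis=0), 0.0)
    adapted = adaptation_stage(env, env_rate)
    return modulation_stage(adapted, env_rate, mode, fb)
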