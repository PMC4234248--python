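"""Processing conditions: nonlinear frequency compression and MUSHRA anchors.

Nonlinear frequency compression (NFC) leaves frequencies below a cutoff
``F_c`` untouched and compresses the band above it.  With compression
exponent ``p = 1/CR`` the input/output frequency map is

    F_out = F_in                      for F_in <= F_c
    F_out = F_c**(1-p) * F_in**p      for F_in  > F_c

i.e. linear compression by CR on a log-frequency axis above the knee.  The
signal-domain processor realizes this map by short-time spectral remapping.

The two anchor degradations frame the low end of a MUSHRA rating scale: a
10th-order 2 kHz Butterworth lowpass, and hard clipping at 25% of the
stimulus peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal, DegenerateInputError

__all__ = [
    "NFCSettings",
    "STANDARD_NFC_CONDITIONS",
    "map_frequency",
    "nfc_process",
    "lowpass_anchor",
    "clip_anchor",
]


@dataclass(frozen=True)
class NFCSettings:
    """Cutoff frequency and compression ratio of an NFC processor.

    ``compression_ratio`` is CR = 1/p where p is the compression exponent.
    CR = 1 makes the frequency map the identity.
    """

    cutoff_hz: float
    compression_ratio: float

    def __post_init__(self):
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if not self.compression_ratio >= 1:
            raise ValueError("compression_ratio must be >= 1")

    @property
    def exponent(self) -> float:
        return 1.0 / self.compression_ratio


#: The five NFC study conditions, labelled crX-fcYk by ratio and cutoff.
STANDARD_NFC_CONDITIONS: dict[str, NFCSettings] = {
    "cr2-fc4k": NFCSettings(4000.0, 2.0),
    "cr2-fc3k": NFCSettings(3000.0, 2.0),
    "cr6-fc3k": NFCSettings(3000.0, 6.0),
    "cr10-fc3k": NFCSettings(3000.0, 10.0),
    "cr2-fc2k": NFCSettings(2000.0, 2.0),
}


def map_frequency(f_in_hz, settings: NFCSettings):
    """Map input frequency (Hz) to output frequency under NFC.

    Identity below the cutoff; the power-law compression above it.  Continuous
    and non-decreasing.  Accepts scalars or arrays.
    """
    f = np.asarray(f_in_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    p = settings.exponent
    fc = settings.cutoff_hz
    out = np.where(f <= fc, f, fc ** (1.0 - p) * np.power(np.maximum(f, fc), p))
    return float(out) if np.isscalar(f_in_hz) else out


def _piecewise_linear_map(f, settings: NFCSettings):
    """Alternative map for sensitivity checks: linear compression above the knee."""
    fc, cr = settings.cutoff_hz, settings.compression_ratio
    f = np.asarray(f, dtype=np.float64)
    return np.where(f <= fc, f, fc + (f - fc) / cr)


def nfc_process(
    signal: AudioSignal,
    settings: NFCSettings,
    frame_len: int = 1024,
    hop: int = 256,
    linear_map: bool = False,
) -> AudioSignal:
    """Apply nonlinear frequency compression by STFT bin remapping.

    Each analysis bin's complex value is relocated to the mapped frequency,
    split linearly between the two nearest target bins (phase taken from the
    source bin); the frame is then resynthesized by overlap-add.  Energy below
    the cutoff is untouched up to windowing tolerance.
    """
    fs = signal.sample_rate_hz
    if settings.cutoff_hz >= fs / 2:
        raise ValueError(
            f"NFC cutoff {settings.cutoff_hz} Hz must lie below Nyquist {fs / 2} Hz"
        )
    win = sps.windows.hann(frame_len, sym=False)
    stft = sps.ShortTimeFFT(win, hop=hop, fs=fs, fft_mode="onesided")
    spec = stft.stft(signal.samples)  # (freq, time)

    freqs = stft.f
    mapper = _piecewise_linear_map if linear_map else map_frequency
    target = np.asarray(mapper(freqs, settings), dtype=np.float64)
    binw = fs / frame_len
    pos = target / binw
    lo = np.floor(pos).astype(int)
    w_hi = pos - lo
    hi = np.minimum(lo + 1, freqs.size - 1)
    lo = np.minimum(lo, freqs.size - 1)

    # phase-vocoder rotation: relocated components must advance at the target
    # frequency across frames, or overlap-add partially cancels and smears
    n_frames = spec.shape[1]
    dphi = 2.0 * np.pi * (target - freqs) * hop / fs
    rot = np.exp(1j * np.outer(dphi, np.arange(n_frames)))
    spec = spec * rot

    out = np.zeros_like(spec)
    # accumulate complex bin values at the mapped positions, per frame
    for t in range(n_frames):
        col = spec[:, t]
        np.add.at(out[:, t], lo, col * (1.0 - w_hi))
        np.add.at(out[:, t], hi, col * w_hi)

    y = np.real(stft.istft(out, k1=signal.n_samples))[: signal.n_samples]

    # the map sends nothing above map_frequency(Nyquist); remove the residual
    # overlap-add splatter beyond it with a zero-delay linear-phase lowpass
    lim = float(mapper(fs / 2, settings))
    if lim < fs / 2 - binw:
        ntaps = 1025
        h = sps.firwin(ntaps, min(lim + 2 * binw, fs / 2 * 0.999), fs=fs)
        y = sps.convolve(np.pad(y, (ntaps // 2, ntaps // 2)), h, mode="valid")[
            : signal.n_samples
        ]
    return signal.with_samples(y)


def lowpass_anchor(signal: AudioSignal, order: int = 10, fc_hz: float = 2000.0) -> AudioSignal:
    """Butterworth lowpass anchor: -3 dB at ``fc_hz``, unit gain at DC."""
    if not fc_hz < signal.sample_rate_hz / 2:
        raise ValueError("lowpass cutoff must lie below Nyquist")
    sos = sps.butter(order, fc_hz, btype="low", fs=signal.sample_rate_hz, output="sos")
    return signal.with_samples(sps.sosfilt(sos, signal.samples))


def clip_anchor(signal: AudioSignal, fraction: float = 0.25) -> AudioSignal:
    """Hard-clip at ``fraction`` of the stimulus' own peak amplitude.

    The threshold is taken from the observed peak of the input, so the output
    peak equals exactly ``fraction * max|samples|``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise DegenerateInputError("cannot clip a silent signal")
    t = fraction * peak
    return signal.with_samples(np.clip(signal.samples, -t, t))
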