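"""Frame-based LPC-domain quality distances: ISD, LAR, LLR, WSSD.

Signals are analysed narrowband (downsampled to 8 kHz, 32 ms Hamming frames,
hop 16 ms, prediction order 10).  Frame distances are aggregated by a trimmed
mean over the lowest 95% of frames to bound outliers; silent frames (below
-60 dBFS in either signal) are excluded jointly.

ISD and LLR are asymmetric in (reference, test); LAR and WSSD are symmetric.
All four are nonnegative and zero on identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import toeplitz

from .audio import AudioSignal, resample

__all__ = [
    "LPCFrame",
    "lpc_analyze",
    "isd",
    "lar",
    "llr",
    "wssd_frame",
    "lpc_distance",
    "LPC_MEASURES",
]

ANALYSIS_RATE_HZ = 8000.0
FRAME_LEN_S = 0.032
HOP_S = 0.016
LPC_ORDER = 10
SILENCE_DBFS = -60.0
TRIM_FRACTION = 0.95

LPC_MEASURES = ("isd", "lar", "llr", "wssd")


@dataclass(frozen=True)
class LPCFrame:
    """All-pole model of one analysis frame.

    ``coefficients`` holds the prediction polynomial a = [1, a_1, ..., a_P]
    (synthesis filter 1/A(z)); ``gain`` is the residual energy;``reflection``
    the Levinson reflection coefficients; ``autocorrelation`` the biased
    autocorrelation at lags 0..P.
    """

    coefficients: np.ndarray
    gain: float
    reflection: np.ndarray | None = None
    autocorrelation: np.ndarray | None = None

    @property
    def order(self) -> int:
        return self.coefficients.size - 1


def _levinson(r: np.ndarray, order: int):
    """Levinson-Durbin recursion: prediction polynomial, reflection coeffs, error."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    k = np.zeros(order)
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[1:i][::-1]
        ki = -acc / err
        k[i - 1] = ki
        a[1 : i + 1] += ki * np.concatenate([a[1:i][::-1], [1.0]])
        err *= 1.0 - ki * ki
        if err <= 0:
            err = np.finfo(float).tiny
    return a, k, err


def lpc_analyze(frame: np.ndarray, order: int = LPC_ORDER) -> LPCFrame | None:
    """Autocorrelation-method LPC of one frame.

    Returns ``None`` for (near-)zero-energy frames, which are excluded from
    the distance averages.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.size <= order:
        raise ValueError("frame must be longer than the prediction order")
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order] / x.size
    if r[0] <= 0:
        return None
    a, k, err = _levinson(r, order)
    return LPCFrame(a, float(err), k, r)


# -- frame distances --------------------------------------------------------

_N_FREQ = 512  # spectral grid; all-pole spectra of order <= 10 are smooth


def _allpole_spectrum(frame: LPCFrame, n: int = _N_FREQ) -> np.ndarray:
    # whole-circle grid: the plain mean is then an exact periodic quadrature
    w, h = sps.freqz(1.0, frame.coefficients, worN=2 * n, whole=True)
    return frame.gain * np.abs(h) ** 2


def isd(ref: LPCFrame, test: LPCFrame) -> float:
    """Itakura-Saito distortion between the two all-pole spectra.

    Mean over frequency of P_r/P_t - log(P_r/P_t) - 1; nonnegative, zero iff
    the spectra coincide, asymmetric in its arguments.
    """
    if ref.order != test.order:
        raise ValueError("frames must have equal prediction orders")
    q = _allpole_spectrum(ref) / _allpole_spectrum(test)
    return float(np.mean(q - np.log(q) - 1.0))


def llr(ref: LPCFrame, test: LPCFrame) -> float:
    """Log-likelihood ratio: log of the prediction-error ratio of the test
    polynomial vs. the reference polynomial on the reference autocorrelation."""
    if ref.autocorrelation is None:
        raise ValueError("llr needs the reference autocorrelation")
    R = toeplitz(ref.autocorrelation)
    a_r, a_t = ref.coefficients, test.coefficients
    num = float(a_t @ R @ a_t)
    den = float(a_r @ R @ a_r)
    if den <= 0 or num <= 0:
        raise ValueError("invalid (non-positive) prediction error")
    return float(np.log(num / den))


def lar(ref: LPCFrame, test: LPCFrame) -> float:
    """RMS difference of log-area ratios, from the reflection coefficients."""
    for fr in (ref, test):
        if fr.reflection is None:
            raise ValueError("lar needs reflection coefficients")
        if np.any(np.abs(fr.reflection) >= 1):
            raise ValueError("invalid frame: |reflection coefficient| >= 1")
    g_r = np.log((1.0 + ref.reflection) / (1.0 - ref.reflection))
    g_t = np.log((1.0 + test.reflection) / (1.0 - test.reflection))
    return float(np.sqrt(np.mean((g_r - g_t) ** 2)))


# -- WSSD -------------------------------------------------------------------

_KMAX = 20.0
_KLOCMAX = 1.0
_N_BARK_FFT = 512


def _bark(f_hz):
    return 13.0 * np.arctan(0.00076 * f_hz) + 3.5 * np.arctan((f_hz / 7500.0) ** 2)


def _critical_band_energies(frame: np.ndarray, fs: float, n_bands: int) -> np.ndarray:
    spec = np.abs(np.fft.rfft(frame, _N_BARK_FFT)) ** 2
    freqs = np.fft.rfftfreq(_N_BARK_FFT, 1.0 / fs)
    z = _bark(freqs)
    edges = np.linspace(0.0, _bark(fs / 2), n_bands + 1)
    e = np.empty(n_bands)
    for b in range(n_bands):
        m = (z >= edges[b]) & (z < edges[b + 1])
        e[b] = spec[m].sum() if np.any(m) else 0.0
    return e


def wssd_frame(
    band_db_ref: np.ndarray, band_db_test: np.ndarray
) -> float:
    """Weighted spectral slope distance of one frame from critical-band
    log-magnitude spectra (dB).

    Adjacent-band slope differences are weighted by peak-proximity weights:
    bands near the global maximum and near their nearest local maximum weigh
    most (weights from the reference spectrum).  Invariant to a common gain
    offset applied to both spectra.
    """
    b_r, b_t = np.asarray(band_db_ref, float), np.asarray(band_db_test, float)
    if b_r.shape != b_t.shape or b_r.ndim != 1 or b_r.size < 3:
        raise ValueError("need two equal-length band spectra with >= 3 bands")
    s_r, s_t = np.diff(b_r), np.diff(b_t)

    glob_max = b_r.max()
    # nearest local maximum: walk up the flank the band sits on (forward on a
    # rising slope, backward on a falling one)
    loc = np.empty(b_r.size - 1)
    for k in range(b_r.size - 1):
        j = k
        if s_r[k] > 0:
            while j + 1 < b_r.size and b_r[j + 1] > b_r[j]:
                j += 1
        else:
            while j - 1 >= 0 and b_r[j - 1] > b_r[j]:
                j -= 1
        loc[k] = b_r[j]
    w = (_KMAX / (_KMAX + glob_max - b_r[:-1])) * (_KLOCMAX / (_KLOCMAX + loc - b_r[:-1]))
    return float(np.sum(w * (s_r - s_t) ** 2) / np.sum(w))


# -- signal-level aggregation ----------------------------------------------

def _frames(x: np.ndarray, fs: float):
    flen = int(round(FRAME_LEN_S * fs))
    hop = int(round(HOP_S * fs))
    win = sps.windows.hamming(flen, sym=False)
    n = 1 + max(0, (x.size - flen) // hop)
    for i in range(n):
        yield x[i * hop : i * hop + flen] * win


def _trimmed_mean(d: np.ndarray, frac: float = TRIM_FRACTION) -> float:
    if d.size == 0:
        raise ValueError("no valid frames to average")
    k = max(1, int(np.floor(frac * d.size)))
    return float(np.mean(np.sort(d)[:k]))


def lpc_distance(
    ref: AudioSignal,
    test: AudioSignal,
    measure: str,
    order: int = LPC_ORDER,
    bandwidth_hz: float = ANALYSIS_RATE_HZ / 2,
) -> float:
    """Frame-averaged LPC-domain distance between two aligned signals.

    ``measure`` is one of ``isd``, ``lar``, ``llr``, ``wssd``.  The default
    analysis band is 0-4 kHz; pass ``bandwidth_hz=8000`` for the wideband
    variant.
    """
    if measure not in LPC_MEASURES:
        raise ValueError(f"measure must be one of {LPC_MEASURES}")
    fs = 2.0 * bandwidth_hz
    r = resample(ref, fs).samples
    t = resample(test, fs).samples
    n = min(r.size, t.size)
    r, t = r[:n], t[:n]

    peak = max(np.max(np.abs(r)), np.max(np.abs(t)), np.finfo(float).tiny)
    sil = 10.0 ** (SILENCE_DBFS / 20.0) * peak

    dists = []
    n_bands = max(3, int(np.floor(_bark(fs / 2))))
    for fr_r, fr_t in zip(_frames(r, fs), _frames(t, fs)):
        if np.sqrt(np.mean(fr_r**2)) < sil or np.sqrt(np.mean(fr_t**2)) < sil:
            continue
        if measure == "wssd":
            eps = np.finfo(float).tiny
            b_r = 10.0 * np.log10(_critical_band_energies(fr_r, fs, n_bands) + eps)
            b_t = 10.0 * np.log10(_critical_band_energies(fr_t, fs, n_bands) + eps)
            dists.append(wssd_frame(b_r, b_t))
            continue
        lp_r = lpc_analyze(fr_r, order)
        lp_t = lpc_analyze(fr_t, order)
        if lp_r is None or lp_t is None:
            continue
        fn = {"isd": isd, "lar": lar, "llr": llr}[measure]
        try:
            dists.append(fn(lp_r, lp_t))
        except ValueError:
            continue  # invalid frame, excluded
    return _trimmed_mean(np.asarray(dists))
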