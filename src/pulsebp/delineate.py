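"""Baseline removal, pacing-spike suppression and fiducial delineation.

ECG delineation follows the dyadic-wavelet (algorithme-a-trous) scheme:
the signal is convolved with a cascade of a quadratic-spline smoothing
filter and a two-tap derivative filter, giving smoothed-derivative
details at scales 2^1..2^4.  R peaks are zero crossings between
opposite-sign modulus-maxima pairs at scale 2^2; QRS bounds and T end
come from threshold crossings at scales 2^2 and 2^4 respectively.

Pulse (SpO2/ABP) onsets use a slope-sum function applied twice, with
threshold-crossing candidate selection and the local minimum preceding
each onset taken as the pulse valley.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import firwin

FS = 250.0

# smoothing (quadratic spline) and derivative prototype filters
_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
_G = np.array([2.0, -2.0])

_REFRACTORY_S = 0.200


@dataclass
class EcgFiducials:
    """Per-beat ECG landmarks (sample indices); NaN-free, aligned arrays."""

    r_peak: np.ndarray
    qrs_onset: np.ndarray
    qrs_offset: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    t_amplitude: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.r_peak)

    @property
    def qt_samples(self) -> np.ndarray:
        return self.t_end - self.qrs_onset

    @classmethod
    def empty(cls):
        z = np.zeros(0, dtype=int)
        return cls(z, z, z, z, z, np.zeros(0))


@dataclass
class PulseFiducials:
    """Per-beat pulse landmarks; beat k spans [valley[k], valley[k+1])."""

    valley: np.ndarray
    peak: np.ndarray = field(default=None)
    min_amp: np.ndarray = field(default=None)
    max_amp: np.ndarray = field(default=None)

    @property
    def n_beats(self) -> int:
        # the final valley only closes the previous beat
        return max(0, len(self.valley) - 1)

    @classmethod
    def empty(cls):
        z = np.zeros(0, dtype=int)
        return cls(z, z, np.zeros(0), np.zeros(0))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def remove_baseline_wander(ecg_lead: np.ndarray) -> np.ndarray:
    """Two-stage median-filter baseline estimate (200 ms then 600 ms),
    subtracted from the signal.  Kernel sizes are standard picks at
    250 Hz: the first removes QRS complexes, the second P/T waves,
    leaving only the slow drift."""
    x = np.asarray(ecg_lead, dtype=float)
    if x.size == 0:
        return x.copy()
    k1 = int(0.200 * FS) | 1   # odd kernels
    k2 = int(0.600 * FS) | 1
    stage1 = median_filter(x, size=k1, mode="nearest")
    baseline = median_filter(stage1, size=k2, mode="nearest")
    return x - baseline


def suppress_pacing_spikes(ecg_lead: np.ndarray, paced: bool) -> np.ndarray:
    """51-tap low-pass FIR (15 Hz cutoff) applied only for paced subjects
    and only for the delineation pass; identity otherwise."""
    if not paced:
        return np.asarray(ecg_lead, dtype=float)
    taps = firwin(51, 15.0, fs=FS)
    return np.convolve(ecg_lead, taps, mode="same")


# ---------------------------------------------------------------------------
# Dyadic wavelet details
# ---------------------------------------------------------------------------

def _equivalent_filters(max_scale: int = 4):
    """Equivalent FIR filter for each detail scale of the a-trous cascade."""
    filters = []
    smooth = np.array([1.0])
    for k in range(1, max_scale + 1):
        up = 2 ** (k - 1)
        g_k = np.zeros((len(_G) - 1) * up + 1)
        g_k[::up] = _G
        filters.append(np.convolve(smooth, g_k))
        h_k = np.zeros((len(_H) - 1) * up + 1)
        h_k[::up] = _H
        smooth = np.convolve(smooth, h_k)
    return filters


_FILTERS = _equivalent_filters(4)


def wavelet_details(x: np.ndarray, scales=(1, 2, 3, 4)) -> dict:
    """Smoothed-derivative detail signals, center-aligned with the input."""
    x = np.asarray(x, dtype=float)
    out = {}
    for s in scales:
        q = _FILTERS[s - 1]
        w = np.convolve(x, q, mode="full")
        off = (len(q) - 1) // 2
        out[s] = w[off:off + len(x)]
    return out


def _local_modulus_maxima(w: np.ndarray, thr: float):
    """Indices of local extrema of w with |w| > thr."""
    dw = np.diff(w)
    idx = np.where((np.sign(dw[:-1]) != np.sign(dw[1:])) & (np.abs(w[1:-1]) > thr))[0] + 1
    return idx


# ---------------------------------------------------------------------------
# ECG delineation
# ---------------------------------------------------------------------------

def _detect_r_peaks(x: np.ndarray, w2: np.ndarray) -> np.ndarray:
    thr = 2.0 * np.sqrt(np.mean(w2 ** 2))
    mm = _local_modulus_maxima(w2, thr)
    if len(mm) == 0:
        return np.zeros(0, dtype=int)
    refr = int(_REFRACTORY_S * FS)
    peaks = []
    i = 0
    while i < len(mm) - 1:
        a, b = mm[i], mm[i + 1]
        # opposite-sign pair within 100 ms brackets a QRS
        if w2[a] * w2[b] < 0 and (b - a) <= int(0.100 * FS):
            seg = x[a:b + 1]
            if len(seg):
                zc = a + int(np.argmax(np.abs(seg)))
                lo = max(0, zc - 6)
                hi = min(len(x), zc + 7)
                r = lo + int(np.argmax(np.abs(x[lo:hi])))
                if not peaks or r - peaks[-1] > refr:
                    peaks.append(r)
                elif np.abs(x[r]) > np.abs(x[peaks[-1]]):
                    peaks[-1] = r
            i += 2
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _qrs_bounds(w2: np.ndarray, r: int):
    win = int(0.120 * FS)
    lo = max(0, r - win)
    hi = min(len(w2), r + win)
    local_max = np.max(np.abs(w2[lo:hi]))
    thr = 0.05 * local_max
    onset = lo
    for i in range(r, lo, -1):
        if abs(w2[i]) < thr and abs(w2[i - 1]) < thr:
            onset = i
            break
    offset = hi - 1
    for i in range(r, hi - 1):
        if abs(w2[i]) < thr and abs(w2[i + 1]) < thr:
            offset = i
            break
    return onset, offset


# |w4| threshold relative to the post-T-peak modulus max; calibrated so
# the crossing sits ~2 sigma after the T apex of a smooth T wave
_T_END_FACTOR = 0.58


def _t_wave(x, w4, r, rr_samples, qrs_off):
    lo = max(qrs_off + int(0.040 * FS), r + int(0.100 * FS))
    hi = min(len(x) - 1, r + int(min(0.6 * rr_samples, 0.450 * FS)))
    if hi - lo < int(0.080 * FS):
        return None
    seg = w4[lo:hi]
    thr = 0.25 * np.max(np.abs(seg)) if np.max(np.abs(seg)) > 0 else 0.0
    mm = _local_modulus_maxima(seg, thr)
    if len(mm) < 2:
        return None
    # main opposite-sign pair with the largest combined modulus
    best = None
    for i in range(len(mm) - 1):
        a, b = mm[i], mm[i + 1]
        if seg[a] * seg[b] < 0:
            score = abs(seg[a]) + abs(seg[b])
            if best is None or score > best[0]:
                best = (score, a, b)
    if best is None:
        return None
    _, a, b = best
    inner = x[lo + a:lo + b + 1]
    t_peak = lo + a + int(np.argmax(np.abs(inner - np.median(x))))
    # T end: |w4| falls below a fixed fraction of the trailing modulus max
    tail_mm = lo + b
    thr_end = _T_END_FACTOR * abs(w4[tail_mm])
    t_end = None
    for i in range(tail_mm, min(len(w4), tail_mm + int(0.200 * FS))):
        if abs(w4[i]) < thr_end:
            t_end = i
            break
    if t_end is None:
        t_end = min(len(x) - 1, tail_mm + int(0.100 * FS))
    return t_peak, t_end


def delineate_ecg(ecg_lead: np.ndarray) -> EcgFiducials:
    """Locate R peaks, QRS bounds, T peak / T end on one baseline-corrected
    lead.  Emits empty fiducials with a warning when no beats are found."""
    x = np.asarray(ecg_lead, dtype=float)
    if x.size < int(0.5 * FS) or np.ptp(x) == 0:
        warnings.warn("no beats found during ECG delineation", stacklevel=2)
        return EcgFiducials.empty()
    det = wavelet_details(x, scales=(2, 4))
    w2, w4 = det[2], det[4]
    r_peaks = _detect_r_peaks(x, w2)
    if len(r_peaks) == 0:
        warnings.warn("no beats found during ECG delineation", stacklevel=2)
        return EcgFiducials.empty()

    baseline = np.median(x)
    rr = np.diff(r_peaks)
    default_rr = np.median(rr) if len(rr) else int(0.8 * FS)

    rows = []
    for k, r in enumerate(r_peaks):
        onset, offset = _qrs_bounds(w2, r)
        rr_k = rr[k] if k < len(rr) else default_rr
        tw = _t_wave(x, w4, r, rr_k, offset)
        if tw is None:
            continue
        t_peak, t_end = tw
        rows.append((r, onset, offset, t_peak, t_end, x[t_peak] - baseline))
    if not rows:
        warnings.warn("no complete beats during ECG delineation", stacklevel=2)
        return EcgFiducials.empty()
    arr = np.asarray(rows)
    return EcgFiducials(
        r_peak=arr[:, 0].astype(int),
        qrs_onset=arr[:, 1].astype(int),
        qrs_offset=arr[:, 2].astype(int),
        t_peak=arr[:, 3].astype(int),
        t_end=arr[:, 4].astype(int),
        t_amplitude=arr[:, 5],
    )


# ---------------------------------------------------------------------------
# Pulse delineation (modified slope-sum approach)
# ---------------------------------------------------------------------------

_SSF_WIN = int(0.128 * FS)  # 32 samples


def _ssf(x: np.ndarray) -> np.ndarray:
    d = np.diff(x, prepend=x[0])
    d[d < 0] = 0.0
    c = np.cumsum(d)
    out = np.empty_like(c)
    w = _SSF_WIN
    out[:w] = c[:w]
    out[w:] = c[w:] - c[:-w]
    return out


def detect_pulse_valleys(pulse: np.ndarray) -> PulseFiducials:
    """Valleys/peaks of a pulsatile channel via a double slope-sum
    function.  No low-pass prefilter is applied; candidate onsets come
    from modulus-maxima-style threshold crossings with a 200 ms
    refractory, and each valley is the local minimum preceding the
    onset."""
    x = np.asarray(pulse, dtype=float)
    if x.size < int(1.0 * FS) or np.ptp(x) == 0:
        warnings.warn("insufficient pulses detected", stacklevel=2)
        return PulseFiducials.empty()
    s = _ssf(_ssf(x))
    # threshold initialized from the head of the record
    head = s[:int(min(10.0 * FS, len(s)))]
    thr = 0.3 * np.max(head)
    if thr <= 0:
        warnings.warn("insufficient pulses detected", stacklevel=2)
        return PulseFiducials.empty()
    refr = int(_REFRACTORY_S * FS)
    above = s > thr
    rising = np.where(above[1:] & ~above[:-1])[0] + 1
    onsets = []
    for i in rising:
        if onsets and i - onsets[-1] <= refr:
            continue
        onsets.append(i)
    valleys = []
    for i in onsets:
        lo = max(0, i - int(0.300 * FS))
        v = lo + int(np.argmin(x[lo:i + 1]))
        if not valleys or v - valleys[-1] > refr:
            valleys.append(v)
    if len(valleys) < 2:
        warnings.warn("insufficient pulses detected", stacklevel=2)
        return PulseFiducials.empty()
    valleys = np.asarray(valleys, dtype=int)
    nb = len(valleys) - 1
    peak = np.empty(nb, dtype=int)
    vmin = np.empty(nb)
    vmax = np.empty(nb)
    for k in range(nb):
        seg = x[valleys[k]:valleys[k + 1]]
        peak[k] = valleys[k] + int(np.argmax(seg))
        vmin[k] = seg.min()
        vmax[k] = seg.max()
    return PulseFiducials(valley=valleys, peak=peak, min_amp=vmin, max_amp=vmax)
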