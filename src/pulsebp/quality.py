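"""Signal-quality screening of 4-second windows.

Each channel is cut into 4 s windows with 0.5 s overlap (stride 3.5 s).
Hard screens (flat runs, out-of-physiological-range samples) label a
window noisy outright; surviving windows get six hand-engineered quality
features and a hybrid convolutional classifier verdict.  A time segment
is clean only when every one of the six channels is clean there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, get_window

from .errors import InsufficientBeatsError, InvalidInputError

FS = 250.0
WINDOW_S = 4.0
STRIDE_S = 3.5
WINDOW_N = int(WINDOW_S * FS)   # 1000
STRIDE_N = int(STRIDE_S * FS)   # 875

FLAT_RUN_S = 0.5
SPO2_RANGE = (0.0, 100.0)
ABP_RANGE = (0.0, 250.0)


@dataclass
class QualityWindow:
    channel: str
    start: int            # sample index into the record
    samples: np.ndarray   # exactly WINDOW_N samples

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != WINDOW_N:
            raise InvalidInputError(
                f"quality window must hold {WINDOW_N} samples, got {len(self.samples)}")


@dataclass
class QualityFeatures:
    pm: float = np.nan
    corr_measure: float = np.nan
    e12: float = np.nan
    sharpness: float = np.nan
    dp_stability: float = np.nan
    peak_stability: float = np.nan
    flat_flag: bool = False
    range_flag: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([
            self.pm, self.corr_measure, self.e12, self.sharpness,
            self.dp_stability, self.peak_stability,
            float(self.flat_flag), float(self.range_flag),
        ])


N_HAND_FEATURES = 8


def segment_quality_windows(record) -> dict:
    """4 s windows per channel, starting at 0 s, 3.5 s, 7 s, ...; a final
    partial window is dropped.  Records shorter than 4 s yield an empty
    list with a warning."""
    n = record.n_samples
    out = {}
    if n < WINDOW_N:
        warnings.warn("record shorter than 4 s: no quality windows", stacklevel=2)
        return {name: [] for name in record.channels()}
    starts = list(range(0, n - WINDOW_N + 1, STRIDE_N))
    for name, x in record.channels().items():
        out[name] = [QualityWindow(name, s, x[s:s + WINDOW_N]) for s in starts]
    return out


def screen_hard_artifacts(window: QualityWindow, channel_kind: str):
    """(flat_flag, range_flag) hard screens; either one marks the window
    noisy and skips the classifier."""
    x = window.samples
    flat_flag = _longest_flat_run(x) >= int(FLAT_RUN_S * FS)
    if channel_kind == "spo2":
        lo, hi = SPO2_RANGE
        range_flag = bool(np.any((x < lo) | (x > hi)))
        flat_flag = flat_flag or _rail_run(x, lo, hi)
    elif channel_kind == "abp":
        lo, hi = ABP_RANGE
        range_flag = bool(np.any((x < lo) | (x > hi)))
        flat_flag = flat_flag or _rail_run(x, lo, hi)
    else:
        range_flag = False
    return bool(flat_flag), bool(range_flag)


def _longest_flat_run(x: np.ndarray) -> int:
    # identical within one quantization step; step estimated from the data
    d = np.abs(np.diff(x))
    pos = d[d > 0]
    tol = pos.min() if len(pos) else 0.0
    flat = d <= tol * 1.0 if len(pos) else np.ones(len(d), bool)
    if not flat.any():
        return 1
    best = cur = 1
    for f in flat:
        cur = cur + 1 if f else 1
        best = max(best, cur)
    return best


def _rail_run(x, lo, hi) -> bool:
    run = int(FLAT_RUN_S * FS)
    for rail in (lo, hi):
        pinned = np.isclose(x, rail)
        if pinned.sum() >= run:
            cur = best = 0
            for p in pinned:
                cur = cur + 1 if p else 0
                best = max(best, cur)
            if best >= run:
                return True
    return False


def periodicity_measure(rr_intervals) -> float:
    """100 - 100*sd(I)/mean(I) over the R-R interval vector; 100 means a
    perfectly regular rhythm.  Sample (n-1) standard deviation."""
    rr = np.asarray(rr_intervals, dtype=float)
    if len(rr) < 2:
        raise InsufficientBeatsError("periodicity measure needs >= 2 intervals")
    mean = rr.mean()
    if mean == 0:
        raise InvalidInputError("mean R-R interval is zero")
    return 100.0 - 100.0 * rr.std(ddof=1) / mean


_QRS_HALF = int(0.060 * FS)   # +-60 ms around R


def sqi_features(window: QualityWindow, r_peaks) -> QualityFeatures:
    """Hand-engineered quality features for one window.

    ``r_peaks`` are sample indices *within the window* (R peaks for ECG,
    pulse peaks for SpO2/ABP).  Features that need >= 2 beats are left
    NaN when beats are missing.
    """
    x = window.samples
    r = np.asarray(r_peaks, dtype=int)
    if np.any((r < 0) | (r >= WINDOW_N)):
        raise IndexError("r_peaks outside window")
    f = QualityFeatures()
    f.e12 = _max_energy_beyond_12hz(x)

    if len(r) >= 2:
        rr = np.diff(r) / FS
        if len(rr) >= 2:
            f.pm = periodicity_measure(rr)
        f.corr_measure = _qrs_correlation(x, r)
        f.sharpness = _sharpness(x, r)
        f.peak_stability = _stability(x[r])
        f.dp_stability = _stability(_delta_p(x, r))
    return f


def _max_energy_beyond_12hz(x: np.ndarray) -> float:
    # Hann-windowed periodogram normalized by window energy
    w = get_window("hann", len(x))
    xz = (x - x.mean()) * w
    p = np.abs(np.fft.rfft(xz)) ** 2
    tot = p.sum()
    if tot == 0:
        return 0.0
    p /= tot
    freqs = np.fft.rfftfreq(len(x), 1 / FS)
    sel = p[freqs >= 12.0]
    return float(sel.max()) if len(sel) else 0.0


def _qrs_correlation(x, r) -> float:
    half = int(0.060 * FS)
    snips = []
    for rk in r:
        if rk - half >= 0 and rk + half < len(x):
            snips.append(x[rk - half:rk + half + 1])
    if len(snips) < 2:
        return np.nan
    cors = []
    for a, b in zip(snips[:-1], snips[1:]):
        sa, sb = a - a.mean(), b - b.mean()
        denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
        if denom > 0:
            cors.append(float((sa * sb).sum() / denom))
    return float(np.mean(cors)) if cors else np.nan


def _sharpness(x, r) -> float:
    """(2/pi)*arctan(S_bar): mean per-beat max |first difference| within
    +-60 ms of the peak, normalized by that beat's peak-to-peak range."""
    vals = []
    for rk in r:
        lo = max(0, rk - _QRS_HALF)
        hi = min(len(x), rk + _QRS_HALF + 1)
        seg = x[lo:hi]
        ptp = np.ptp(seg)
        if ptp > 0 and len(seg) > 1:
            vals.append(np.max(np.abs(np.diff(seg))) / ptp)
    if not vals:
        return np.nan
    return float((2.0 / np.pi) * np.arctan(np.mean(vals)))


def _delta_p(x, r) -> np.ndarray:
    """Per-beat max-min amplitude between consecutive R midpoints."""
    mids = ((r[:-1] + r[1:]) // 2)
    bounds = np.concatenate(([0], mids, [len(x)]))
    return np.array([np.ptp(x[a:b]) for a, b in zip(bounds[:-1], bounds[1:]) if b > a])


def _stability(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    if len(v) < 2 or np.mean(v) == 0:
        return np.nan
    return float(1.0 - v.std(ddof=1) / np.abs(v.mean()))


def window_peaks(window: QualityWindow, channel_kind: str) -> np.ndarray:
    """Rough beat peaks inside a window, used to feed sqi_features."""
    x = window.samples
    if np.ptp(x) == 0:
        return np.zeros(0, dtype=int)
    if channel_kind == "ecg":
        height = x.mean() + 0.5 * (x.max() - x.mean())
    else:
        height = x.mean()
    peaks, _ = find_peaks(x, height=height, distance=int(0.3 * FS))
    return peaks


def hand_feature_matrix(windows, channel_kinds) -> np.ndarray:
    """Stack hand features (NaN -> 0 with validity untouched) for a list
    of windows; used as the classifier's side input."""
    rows = []
    for w in windows:
        kind = channel_kinds[w.channel]
        flat, rng = screen_hard_artifacts(w, kind)
        feats = sqi_features(w, window_peaks(w, kind))
        feats.flat_flag, feats.range_flag = flat, rng
        arr = feats.as_array()
        arr[np.isnan(arr)] = 0.0
        rows.append(arr)
    return np.asarray(rows)


def fuse_segments(labels_per_channel: dict) -> np.ndarray:
    """Fuse per-channel window verdicts: window index i is clean iff every
    channel's window i is clean.  Monotone: flipping any window to noisy
    can only shrink the clean set."""
    mats = [np.asarray(v, dtype=bool) for v in labels_per_channel.values()]
    n = min(len(m) for m in mats)
    out = np.ones(n, dtype=bool)
    for m in mats:
        out &= m[:n]
    return out


def clean_sample_mask(n_samples: int, window_clean: np.ndarray) -> np.ndarray:
    """Expand fused window verdicts to a per-sample mask: a sample is
    clean iff no noisy window covers it."""
    mask = np.ones(n_samples, dtype=bool)
    covered = np.zeros(n_samples, dtype=bool)
    for i, clean in enumerate(window_clean):
        s = i * STRIDE_N
        e = min(n_samples, s + WINDOW_N)
        covered[s:e] = True
        if not clean:
            mask[s:e] = False
    mask &= covered
    return mask
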