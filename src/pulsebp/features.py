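"""The 48-entry feature vector per beat sequence and feature selection.

Schema (fixed order):
  per ECG lead 1..4: mobility, complexity, fractal, entropy, autocorr,
      qtc (s), t_amp (mV)                                  -> 28 entries
  SpO2: kte_mean, kte_var, kte_iqr, kte_skew,
      spectral_entropy, ar1..ar5                           -> 10 entries
  timing: heart_rate (bpm), pat (s), t2spo2 (s)            ->  3 entries
  demographics: age, bmi, gender_code,
      race_white, race_hispanic, race_asian, race_black    ->  7 entries

Values are left on their physical scales (no normalization); components
that cannot be computed carry NaN missing markers, which the model layer
imputes with training medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.stats import skew

from .errors import InvalidInputError

FS = 250.0
ENTROPY_BINS = 32
HIGUCHI_KMAX = 8
AR_ORDER = 5

_PER_LEAD = ("mobility", "complexity", "fractal", "entropy", "autocorr", "qtc", "t_amp")
_SPO2 = ("kte_mean", "kte_var", "kte_iqr", "kte_skew", "spectral_entropy",
         "ar1", "ar2", "ar3", "ar4", "ar5")
_TIMING = ("heart_rate", "pat", "t2spo2")
_DEMO = ("age", "bmi", "gender_code",
         "race_white", "race_hispanic", "race_asian", "race_black")

FEATURE_NAMES = tuple(
    [f"{name}_{lead}" for lead in range(1, 5) for name in _PER_LEAD]
    + list(_SPO2) + list(_TIMING) + list(_DEMO)
)
assert len(FEATURE_NAMES) == 48

#: Features the default selection drops: race + gender + per-lead fractal
#: dimension + the five AR coefficients (14 total, leaving 34).
DEFAULT_EXCLUDED = tuple(
    ["race_white", "race_hispanic", "race_asian", "race_black", "gender_code"]
    + [f"fractal_{lead}" for lead in range(1, 5)]
    + [f"ar{i}" for i in range(1, 6)]
)


# ---------------------------------------------------------------------------
# Scalar signal descriptors
# ---------------------------------------------------------------------------

def hjorth_params(x):
    """(mobility, complexity): S1/S0 and the RMS second difference, with
    S0 = sqrt(sum x^2 / N) and S1 = sqrt(sum d^2 / (N-1)) over first
    differences d."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise InvalidInputError("hjorth_params needs >= 3 samples")
    s0 = np.sqrt(np.sum(x ** 2) / n)
    d = np.diff(x)
    s1 = np.sqrt(np.sum(d ** 2) / (n - 1))
    s2 = np.sqrt(np.sum(np.diff(d) ** 2) / (n - 2))
    mobility = s1 / s0 if s0 > 0 else np.nan
    return mobility, s2


def amplitude_entropy(x, m: int = ENTROPY_BINS) -> float:
    """Shannon entropy (natural log) of the amplitude histogram over m
    equal bins spanning the signal's min-max range; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    if len(x) < m:
        raise InvalidInputError("amplitude_entropy needs length >= bin count")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=m, range=(lo, hi))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def fractal_dimension(x, k_max: int = HIGUCHI_KMAX) -> float:
    """Higuchi fractal dimension; ~1 for smooth curves, ->2 for noise."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 32:
        return np.nan
    if np.ptp(x) == 0:
        return 1.0
    lk = []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk.append(np.mean(lengths))
    lk = np.asarray(lk)
    ks = np.arange(1, k_max + 1)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(1.0 / ks[valid]), np.log(lk[valid]), 1)[0]
    return float(slope)


def autocorr_feature(x, lag: int | None = None) -> float:
    """Biased autocorrelation normalized by total energy, evaluated at the
    window center lag (floor(N/2)) unless another lag is given."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise InvalidInputError("autocorr_feature needs >= 2 samples")
    energy = np.sum(x ** 2)
    if energy == 0:
        return np.nan
    if lag is None:
        lag = n // 2
    if not 0 <= lag < n:
        raise InvalidInputError(f"lag {lag} outside [0, {n})")
    return float(np.sum(x[:n - lag] * x[lag:]) / energy)


def kaiser_teager_energy(s) -> np.ndarray:
    """KTE_i = s_i^2 - s_{i+1}*s_{i-1} for interior samples."""
    s = np.asarray(s, dtype=float)
    if len(s) < 3:
        raise InvalidInputError("KTE needs >= 3 samples")
    return s[1:-1] ** 2 - s[2:] * s[:-2]


def spectral_entropy(x) -> float:
    """Entropy of the normalized FFT power distribution (natural log),
    computed on the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    p = np.abs(np.fft.rfft(x)) ** 2
    tot = p.sum()
    if tot == 0:
        return 0.0
    p = p / tot
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def ar_coefficients(x, order: int = AR_ORDER) -> np.ndarray:
    """Yule-Walker AR(order) coefficients of the mean-removed signal,
    in the convention x_t = a1*x_{t-1} + ... + a_p*x_{t-p} + e_t."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    if n <= order + 1:
        raise InvalidInputError("signal too short for AR fit")
    if np.allclose(x, 0):
        return np.full(order, np.nan)
    r = np.array([np.dot(x[:n - k], x[k:]) / n for k in range(order + 1)])
    return solve_toeplitz(r[:-1], r[1:])


# ---------------------------------------------------------------------------
# Sequence-level feature blocks
# ---------------------------------------------------------------------------

def ecg_beat_features(sequence, lead: int):
    """(qtc, t_amp): Bazett-corrected median QT and median T amplitude for
    one lead across the sequence's beats."""
    qtcs, amps = [], []
    for b in sequence.beats:
        f = b.lead_fid[lead]
        rr = (f["r"] - f["prev_r"]) / FS
        if rr <= 0:
            continue
        qt = (f["t_end"] - f["qrs_onset"]) / FS
        qtcs.append(qt / np.sqrt(rr))
        amps.append(f["t_amp"])
    if not qtcs:
        return np.nan, np.nan
    return float(np.median(qtcs)), float(np.median(amps))


def spo2_features(spo2_segment):
    """KTE summary stats, spectral entropy and AR(5) coefficients of the
    sequence's SpO2 samples."""
    s = np.asarray(spo2_segment, dtype=float)
    if len(s) < 10:
        raise InvalidInputError("spo2_features needs >= 10 samples")
    kte = kaiser_teager_energy(s)
    out = {
        "kte_mean": float(np.mean(kte)),
        "kte_var": float(np.var(kte, ddof=1)),
        "kte_iqr": float(np.subtract(*np.percentile(kte, [75, 25]))),
        "kte_skew": float(skew(kte)) if np.ptp(kte) > 0 else 0.0,
        "spectral_entropy": spectral_entropy(s),
    }
    try:
        ar = ar_coefficients(s)
    except InvalidInputError:
        ar = np.full(AR_ORDER, np.nan)
    for i in range(AR_ORDER):
        out[f"ar{i + 1}"] = float(ar[i])
    return out


def timing_features(sequence):
    """(heart_rate, pat, t2spo2) from matched beats.

    heart_rate: 60 / median R-R across leads and beats (a single-beat
    window uses its instantaneous R-R to the previous beat); pat: mean
    R-peak -> SpO2-peak delay; t2spo2: median signed SpO2-peak - T-end
    delay."""
    rrs, pats, t2s = [], [], []
    for b in sequence.beats:
        for f in b.lead_fid:
            rr = (f["r"] - f["prev_r"]) / FS
            if rr > 0:
                rrs.append(rr)
        pats.append((b.spo2_fid["peak"] - b.r_peak) / FS)
        t2s.append((b.spo2_fid["peak"] - b.ecg_extent[1]) / FS)
    if not rrs or not pats:
        return np.nan, np.nan, np.nan
    hr = 60.0 / float(np.median(rrs))
    return hr, float(np.mean(pats)), float(np.median(t2s))


def encode_demographics(subject) -> dict:
    """gender: 1=female, 2=male, NaN=missing/other; race one-hot in the
    order [White, Hispanic, Asian, Black], all zeros when missing."""
    gender = {"female": 1.0, "male": 2.0}.get(subject.gender, np.nan)
    race = {"race_white": 0.0, "race_hispanic": 0.0,
            "race_asian": 0.0, "race_black": 0.0}
    key = f"race_{subject.race.lower()}"
    if key in race:
        race[key] = 1.0
    return {"age": subject.age, "bmi": subject.bmi,
            "gender_code": gender, **race}


def assemble_feature_vector(sequence, record) -> dict:
    """All 48 named features for one sequence of the given record."""
    out = {}
    start = min(b.ecg_extent[0] for b in sequence.beats)
    end = max(b.ecg_extent[1] for b in sequence.beats)
    for li in range(4):
        x = record.ecg[li, start:end]
        suffix = f"_{li + 1}"
        try:
            mob, comp = hjorth_params(x)
        except InvalidInputError:
            mob, comp = np.nan, np.nan
        out["mobility" + suffix] = mob
        out["complexity" + suffix] = comp
        out["fractal" + suffix] = fractal_dimension(x)
        try:
            out["entropy" + suffix] = amplitude_entropy(x)
        except InvalidInputError:
            out["entropy" + suffix] = np.nan
        try:
            out["autocorr" + suffix] = autocorr_feature(x)
        except InvalidInputError:
            out["autocorr" + suffix] = np.nan
        qtc, t_amp = ecg_beat_features(sequence, li)
        out["qtc" + suffix] = qtc
        out["t_amp" + suffix] = t_amp

    s_start = min(b.spo2_extent[0] for b in sequence.beats)
    s_end = max(b.spo2_extent[1] for b in sequence.beats)
    try:
        out.update(spo2_features(record.spo2[s_start:s_end]))
    except InvalidInputError:
        out.update({k: np.nan for k in _SPO2})

    hr, pat, t2 = timing_features(sequence)
    out.update({"heart_rate": hr, "pat": pat, "t2spo2": t2})
    out.update(encode_demographics(record.subject))

    assert set(out) == set(FEATURE_NAMES)
    return {k: out[k] for k in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    selected: tuple
    excluded: tuple
    importance: dict | None = None

    def __post_init__(self):
        if set(self.selected) | set(self.excluded) != set(FEATURE_NAMES):
            raise InvalidInputError("selection must partition the 48-feature schema")
        if set(self.selected) & set(self.excluded):
            raise InvalidInputError("selected and excluded overlap")


def select_features(importance: dict | None = None,
                    n_keep: int | None = None) -> SelectionReport:
    """Default rule: drop race, gender, per-lead fractal dimension and the
    AR coefficients (34 features remain).  With importance scores given,
    rank by score instead and keep the top ``n_keep``."""
    if importance is None:
        selected = tuple(n for n in FEATURE_NAMES if n not in DEFAULT_EXCLUDED)
        return SelectionReport(selected=selected, excluded=DEFAULT_EXCLUDED)
    if set(importance) != set(FEATURE_NAMES):
        raise InvalidInputError("importance must cover all 48 features")
    if n_keep is None:
        n_keep = 34
    ranked = sorted(FEATURE_NAMES, key=lambda n: -importance[n])
    selected = tuple(sorted(ranked[:n_keep], key=FEATURE_NAMES.index))
    excluded = tuple(n for n in FEATURE_NAMES if n not in selected)
    return SelectionReport(selected=selected, excluded=excluded,
                           importance=dict(importance))
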