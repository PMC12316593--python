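"""Physiologically structured waveform simulator with exact ground truth.

Generates synchronized 4-lead ECG / SpO2 / ABP records in which beat
timing, pulse arrival time and pulse amplitude co-vary with a programmed
systolic/diastolic blood-pressure trajectory, so that downstream
delineation, feature extraction and regression can be validated against
known fiducials and labels.  The pressure->timing mapping is a test
harness, not a physiological claim: PAT_ms = a - b*(systolic - 120)
with b > 0, which is monotone (hence invertible) over the simulated
range.

All randomness flows from a single seed through per-subject
``numpy.random.SeedSequence`` spawning, so cohort generation is
reproducible independent of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InvalidInputError
from .records import DEFAULT_ECG_LEADS, SubjectInfo, WaveformRecord

FS = 250.0

NOISE_TYPES = ("loose_lead", "baseline_wander", "hf_jitter", "flat_saturation")

# per-lead (overall scale, T-wave scale); last lead is precordial
_LEAD_SCALES = ((1.0, 1.0), (1.1, 1.05), (0.6, 0.9), (1.5, 1.3))


@dataclass
class BpTrajectory:
    systolic_base: float = 120.0
    diastolic_base: float = 80.0
    drift_amp: float = 0.0          # mmHg, slow sinusoidal drift
    drift_period_s: float = 120.0
    steps: tuple = ()               # ((time_s, d_sys, d_dia), ...)
    beat_noise_sd: float = 0.0      # mmHg, independent per beat


@dataclass
class SimulationConfig:
    n_subjects: int = 1
    duration_s: float = 60.0
    hr_bpm: float = 60.0
    hr_variability_bpm: float = 0.0   # amplitude of respiratory HR modulation
    hr_jitter_sd_ms: float = 0.0      # white jitter on RR
    bp: BpTrajectory = field(default_factory=BpTrajectory)
    pat_intercept_ms: float = 220.0   # PAT at systolic = 120
    pat_slope_ms_per_mmhg: float = 0.8
    spo2_amp_per_mmhg: float = 0.05   # SpO2 pulse amplitude per mmHg pulse pressure
    subject_sys_offset_sd: float = 0.0
    subject_dia_offset_sd: float = 0.0
    noise_mix: dict = field(default_factory=dict)  # noise_type -> probability
    pace_fraction: float = 0.0
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.duration_s < 2.0:
            raise ConfigError("duration_s too short for a single beat")
        if self.bp.systolic_base <= self.bp.diastolic_base:
            raise ConfigError("systolic must exceed diastolic")
        if self.pat_intercept_ms <= 0:
            raise ConfigError("PAT must be positive")
        for k, p in self.noise_mix.items():
            if k not in NOISE_TYPES:
                raise ConfigError(f"unknown noise type {k!r}")
            if not 0 <= p <= 1:
                raise ConfigError("noise probabilities must be in [0,1]")
        if not 0 <= self.pace_fraction <= 1:
            raise ConfigError("pace_fraction must be in [0,1]")


@dataclass
class GroundTruth:
    """Per-beat fiducials (sample indices at 250 Hz) and labels."""

    r_peak: np.ndarray
    qrs_onset: np.ndarray
    qrs_offset: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    spo2_valley: np.ndarray
    spo2_peak: np.ndarray
    abp_valley: np.ndarray
    abp_peak: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    pat_ms: np.ndarray
    noise_spans: list = field(default_factory=list)  # (channel, start, end, type)

    def __post_init__(self):
        if np.any(np.diff(self.r_peak) <= 0):
            raise InvalidInputError("beat times must be strictly increasing")
        if np.any(self.systolic <= self.diastolic):
            raise InvalidInputError("systolic must exceed diastolic per beat")

    @property
    def n_beats(self) -> int:
        return len(self.r_peak)


def _gauss(n, mu, sigma, amp):
    lo = max(0, int(mu - 5 * sigma))
    hi = min(n, int(mu + 5 * sigma) + 1)
    if hi <= lo:
        return lo, np.zeros(0)
    t = np.arange(lo, hi, dtype=float)
    return lo, amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _cosine_ramp(y0, y1, n):
    """n samples from y0 (inclusive) toward y1 (exclusive), smooth ends."""
    u = np.arange(n, dtype=float) / n
    return y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * u))


def _beat_schedule(cfg: SimulationConfig, rng, n_samples):
    """R-peak sample times with respiratory modulation + white jitter."""
    r = []
    t = 0.30  # first R at 300 ms
    while t * FS < n_samples - FS:  # leave a tail for T wave / pulses
        r.append(int(round(t * FS)))
        hr = cfg.hr_bpm + cfg.hr_variability_bpm * np.sin(2 * np.pi * 0.25 * t)
        rr = 60.0 / hr + rng.normal(0.0, cfg.hr_jitter_sd_ms / 1000.0)
        rr = max(rr, 0.45)
        t += rr
    return np.asarray(r, dtype=int)


def _bp_series(cfg: SimulationConfig, rng, r_peaks, sys_off=0.0, dia_off=0.0):
    t = r_peaks / FS
    bp = cfg.bp
    drift = bp.drift_amp * np.sin(2 * np.pi * t / bp.drift_period_s)
    sys_v = np.full(len(t), bp.systolic_base + sys_off) + drift
    dia_v = np.full(len(t), bp.diastolic_base + dia_off) + 0.5 * drift
    for step_t, d_sys, d_dia in bp.steps:
        mask = t >= step_t
        sys_v[mask] += d_sys
        dia_v[mask] += d_dia
    if bp.beat_noise_sd > 0:
        sys_v += rng.normal(0, bp.beat_noise_sd, len(t))
        dia_v += rng.normal(0, bp.beat_noise_sd, len(t))
    # pulse-pressure floor keeps the construction physiological
    dia_v = np.minimum(dia_v, sys_v - 10.0)
    return sys_v, dia_v


def _sample_demographics(rng):
    gender = ("female", "male")[int(rng.integers(2))]
    race = ("Asian", "Black", "Hispanic", "White")[int(rng.integers(4))]
    return SubjectInfo(
        age=float(np.round(rng.uniform(20, 90), 1)),
        bmi=float(np.round(rng.uniform(16, 45), 1)),
        gender=gender,
        race=race,
    )


def simulate_subject_record(
    config: SimulationConfig,
    subject_index: int = 0,
    *,
    subject_info: SubjectInfo | None = None,
    sys_offset: float = 0.0,
    dia_offset: float = 0.0,
    paced: bool | None = None,
):
    """Build one clean (unless noise_mix requests otherwise) record + truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)
    rng = np.random.default_rng(ss[subject_index % len(ss)])
    n = int(round(config.duration_s * FS))
    r_peaks = _beat_schedule(config, rng, n)
    if len(r_peaks) < 2:
        raise ConfigError("duration too short for two beats")
    sys_v, dia_v = _bp_series(config, rng, r_peaks, sys_offset, dia_offset)

    pat_ms = config.pat_intercept_ms - config.pat_slope_ms_per_mmhg * (sys_v - 120.0)
    pat_ms = np.maximum(pat_ms, 60.0)
    pat_smp = np.round(pat_ms / 1000.0 * FS).astype(int)

    nb = len(r_peaks)
    rr_s = np.empty(nb)
    rr_s[1:] = np.diff(r_peaks) / FS
    rr_s[0] = rr_s[1]

    # --- ECG fiducial layout (identical timing across leads) ---
    sigma_r = 0.012 * FS
    sigma_t = 0.050 * FS
    t_peak = r_peaks + np.round((0.25 * np.sqrt(rr_s)) * FS).astype(int)
    t_end = t_peak + int(round(2.0 * sigma_t))
    qrs_on = r_peaks - int(round(0.040 * FS))
    qrs_off = r_peaks + int(round(0.048 * FS))

    ecg = np.zeros((4, n))
    for li, (scale, t_scale) in enumerate(_LEAD_SCALES):
        for k in range(nb):
            for mu, sig, amp in (
                (r_peaks[k] - 0.160 * FS, 0.020 * FS, 0.10),   # P
                (r_peaks[k] - 0.028 * FS, 0.008 * FS, -0.10),  # Q
                (r_peaks[k], sigma_r, 1.00),                   # R
                (r_peaks[k] + 0.032 * FS, 0.010 * FS, -0.15),  # S
                (t_peak[k], sigma_t, 0.25 * t_scale),          # T
            ):
                lo, w = _gauss(n, mu, sig, amp * scale)
                ecg[li, lo:lo + len(w)] += w

    if paced is None:
        paced = bool(rng.random() < config.pace_fraction)
    if paced:
        spike_at = r_peaks - int(round(0.060 * FS))
        for li in range(4):
            sel = spike_at[(spike_at >= 0) & (spike_at < n)]
            ecg[li, sel] += 5.0

    # --- ABP: valley -> cosine rise to systolic peak -> cosine decay ---
    abp_valley = r_peaks + int(round(0.120 * FS))
    abp_peak = abp_valley + np.maximum(
        np.round(0.25 * rr_s * FS).astype(int), int(0.08 * FS))
    abp = np.empty(n)
    abp[:] = dia_v[0]
    # lead-in: gentle descent to the first valley (avoid flat runs)
    if abp_valley[0] > 0:
        abp[:abp_valley[0]] = np.linspace(
            dia_v[0] + 6.0, dia_v[0], abp_valley[0], endpoint=False)
    for k in range(nb):
        v0, p0 = abp_valley[k], abp_peak[k]
        v1 = abp_valley[k + 1] if k + 1 < nb else n
        p0 = min(p0, v1 - 2)
        abp[v0:p0] = _cosine_ramp(dia_v[k], sys_v[k], p0 - v0)
        abp[p0] = sys_v[k]
        d_next = dia_v[k + 1] if k + 1 < nb else dia_v[k]
        if v1 > p0 + 1:
            abp[p0 + 1:v1] = _cosine_ramp(sys_v[k], d_next, v1 - p0 - 1 + 1)[1:]

    # --- SpO2: pulse peak at R + PAT, valley precedes peak by rise time ---
    rise = int(round(0.100 * FS))
    spo2_peak = r_peaks + pat_smp
    spo2_valley = spo2_peak - rise
    base = 96.0
    amp = config.spo2_amp_per_mmhg * (sys_v - dia_v)
    spo2 = np.empty(n)
    spo2[:] = base
    if spo2_valley[0] > 0:
        spo2[:spo2_valley[0]] = np.linspace(
            base + 0.3, base, spo2_valley[0], endpoint=False)
    for k in range(nb):
        v0, p0 = spo2_valley[k], spo2_peak[k]
        v1 = spo2_valley[k + 1] if k + 1 < nb else n
        if v0 < 0 or p0 >= n:
            continue
        p0 = min(p0, v1 - 2)
        spo2[v0:p0] = _cosine_ramp(base, base + amp[k], p0 - v0)
        spo2[p0] = base + amp[k]
        if v1 > p0 + 1:
            spo2[p0 + 1:v1] = _cosine_ramp(base + amp[k], base, v1 - p0 - 1 + 1)[1:]

    if subject_info is None:
        subject_info = _sample_demographics(rng)

    record = WaveformRecord(
        subject_id=f"sim{subject_index:04d}",
        fs=FS,
        ecg=ecg,
        spo2=spo2,
        abp=abp,
        ecg_leads=DEFAULT_ECG_LEADS,
        subject=subject_info,
        paced=paced,
    )

    # achieved per-beat extremes are the gold standard the pipeline sees
    sys_true = np.empty(nb)
    dia_true = np.empty(nb)
    for k in range(nb):
        v0 = abp_valley[k]
        v1 = abp_valley[k + 1] if k + 1 < nb else n
        seg = abp[v0:v1]
        sys_true[k] = seg.max()
        dia_true[k] = seg.min()

    truth = GroundTruth(
        r_peak=r_peaks, qrs_onset=qrs_on, qrs_offset=qrs_off,
        t_peak=t_peak, t_end=t_end,
        spo2_valley=spo2_valley, spo2_peak=spo2_peak,
        abp_valley=abp_valley, abp_peak=abp_peak,
        systolic=sys_true, diastolic=dia_true, pat_ms=pat_ms,
    )

    for noise_type, prob in config.noise_mix.items():
        if rng.random() < prob:
            ch_names = list(record.channels())
            channel = ch_names[int(rng.integers(len(ch_names)))]
            span_len = int(rng.uniform(4.0, 10.0) * FS)
            start = int(rng.integers(0, max(1, n - span_len)))
            record, labels = inject_noise(
                record, noise_type, channel, (start, start + span_len),
                seed=int(rng.integers(2**31)))
            truth.noise_spans.extend(labels)

    return record, truth


def simulate_cohort(config: SimulationConfig):
    """Simulate ``n_subjects`` records with distinct demographics/BP offsets."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(config.n_subjects + 1)[-1])
    out = []
    for i in range(config.n_subjects):
        sys_off = float(cohort_rng.normal(0, config.subject_sys_offset_sd))
        dia_off = float(cohort_rng.normal(0, config.subject_dia_offset_sd))
        info = _sample_demographics(cohort_rng)
        rec, truth = simulate_subject_record(
            config, i, subject_info=info, sys_offset=sys_off, dia_offset=dia_off)
        out.append((rec, truth))
    return out


def inject_noise(record: WaveformRecord, noise_type: str, channel: str,
                 span, seed: int = 0):
    """Corrupt one channel over ``span = (start, end)`` samples.

    Returns a modified copy plus ``(channel, start, end, type)`` labels
    covering the affected region.  Only the selected channel changes.
    """
    if noise_type not in NOISE_TYPES:
        raise ConfigError(f"unknown noise type {noise_type!r}")
    start, end = int(span[0]), int(span[1])
    n = record.n_samples
    if not (0 <= start < end <= n):
        raise ConfigError(f"span {span} outside record of length {n}")
    channels = record.channels()
    if channel not in channels:
        raise ConfigError(f"unknown channel {channel!r}")

    rng = np.random.default_rng(seed)
    x = channels[channel].copy()
    seg = x[start:end]
    sd = max(np.std(seg), 1e-3)
    m = end - start

    if noise_type == "flat_saturation":
        if channel == "spo2":
            seg[:] = 100.0
        elif channel == "abp":
            seg[:] = 250.0
        else:
            seg[:] = seg[0]
    elif noise_type == "baseline_wander":
        f = rng.uniform(0.15, 0.6)
        t = np.arange(m) / record.fs
        seg += 8.0 * sd * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif noise_type == "hf_jitter":
        seg += rng.normal(0, 1.5 * sd, m)  # ~0 dB SNR relative to local power
    elif noise_type == "loose_lead":
        n_art = max(1, m // int(2 * record.fs))
        for _ in range(n_art):
            a0 = int(rng.integers(start, max(start + 1, end - 50)))
            a1 = min(end, a0 + int(rng.uniform(0.05, 0.5) * record.fs))
            x[a0:a1] += rng.choice([-1, 1]) * rng.uniform(8, 15) * sd
    if noise_type != "loose_lead":
        x[start:end] = seg

    new = replace(record)
    if channel.startswith("ecg_"):
        li = list(record.ecg_leads).index(channel.split("_", 1)[1])
        ecg = record.ecg.copy()
        ecg[li] = x
        new = replace(record, ecg=ecg)
    elif channel == "spo2":
        new = replace(record, spo2=x)
    else:
        new = replace(record, abp=x)
    return new, [(channel, start, end, noise_type)]


def build_noise_corpus(n_windows: int = 2000, seed: int = 0):
    """Labeled 4 s quality-window corpus: half clean, half injected with
    the four noise classes (cycled), channels cycled across the six.

    Returns ``(X, H, y, noise_types)``: raw windows (n, 1000), hand
    features (n, 8), labels (1 = noisy) and the per-window noise type
    ('' for clean).
    """
    from .quality import hand_feature_matrix, segment_quality_windows

    rng = np.random.default_rng(seed)
    X, H, y, types = [], [], [], []
    si = 0
    per_record = 12
    while len(X) < n_windows:
        cfg = SimulationConfig(
            duration_s=49.0, hr_bpm=float(rng.uniform(55, 95)),
            hr_variability_bpm=3.0, hr_jitter_sd_ms=10.0,
            seed=seed + 7919 * si)
        cfg.bp.drift_amp = float(rng.uniform(0, 10))
        rec, _ = simulate_subject_record(cfg, 0)
        make_noisy = si % 2 == 0
        channel = list(rec.channels())[si % 6]
        noise_type = NOISE_TYPES[(si // 2) % 4] if make_noisy else ""
        if make_noisy:
            rec, _ = inject_noise(rec, noise_type, channel,
                                  (0, rec.n_samples),
                                  seed=int(rng.integers(2**31)))
        wins = segment_quality_windows(rec)[channel][:per_record]
        kinds = rec.channel_kinds()
        for w in wins:
            X.append(w.samples)
            H.append(hand_feature_matrix([w], kinds)[0])
            y.append(1.0 if make_noisy else 0.0)
            types.append(noise_type)
            if len(X) >= n_windows:
                break
        si += 1
    return (np.asarray(X), np.asarray(H), np.asarray(y, dtype=float),
            np.asarray(types))


# ---------------------------------------------------------------------------
# Tabular cohort generator for regression-level experiments
# ---------------------------------------------------------------------------

def simulate_feature_cohort(
    n_subjects: int = 20,
    sequences_per_subject: int = 500,
    bp_noise_sd: float = 2.0,
    subject_offset_sd: float = 10.0,
    seed: int = 0,
):
    """Feature-matrix cohort where BP is a smooth function of PAT, heart
    rate and pulse amplitude plus noise, with per-subject offsets.

    Bypasses waveform synthesis: used to exercise the regression layer at
    scale (many sequences per subject) within desk-scale budgets.
    Returns ``(X, y_sys, y_dia, subject_ids)`` with X a DataFrame over the
    full 48-feature schema.
    """
    from .features import FEATURE_NAMES

    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    y_sys, y_dia, subjects = [], [], []
    for s in range(n_subjects):
        off = rng.normal(0, subject_offset_sd)
        # per-subject PAT calibration: the timing->pressure mapping is
        # shared in shape but individually offset, as in real arteries
        pat_cal = rng.normal(0, 16.0)
        age = rng.uniform(20, 90)
        bmi = rng.uniform(16, 45)
        gender = rng.integers(1, 3)
        race = np.zeros(4)
        race[rng.integers(4)] = 1
        for _ in range(sequences_per_subject):
            sys_bp = 120.0 + off + rng.normal(0, 15.0)
            dia_bp = sys_bp - 40.0 + rng.normal(0, 5.0)
            pat_s = (220.0 + pat_cal - 0.8 * (sys_bp - 120.0)) / 1000.0
            hr = 60.0 + 0.15 * (sys_bp - 120.0) + rng.normal(0, 2.0)
            pulse_amp = 0.05 * (sys_bp - dia_bp)
            row = {name: rng.normal(0, 1) for name in FEATURE_NAMES}
            row.update({
                "pat": pat_s + rng.normal(0, 0.002),
                "heart_rate": hr,
                "t2spo2": pat_s - 0.15 + rng.normal(0, 0.004),
                "kte_mean": pulse_amp ** 2 + rng.normal(0, 0.01),
                "age": age, "bmi": bmi, "gender_code": gender,
                "race_white": race[0], "race_hispanic": race[1],
                "race_asian": race[2], "race_black": race[3],
            })
            rows.append(row)
            y_sys.append(sys_bp + rng.normal(0, bp_noise_sd))
            y_dia.append(dia_bp + rng.normal(0, bp_noise_sd))
            subjects.append(f"sim{s:04d}")
    import pandas as pd

    X = pd.DataFrame(rows, columns=FEATURE_NAMES)
    return X, np.asarray(y_sys), np.asarray(y_dia), np.asarray(subjects)
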