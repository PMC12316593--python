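"""Beat extents across channels, sequence assembly and gold-standard BP.

A beat's ECG extent runs from the previous beat's T end to the current
beat's T end (identical across the four leads); SpO2/ABP extents run
between consecutive pulse valleys.  Beats whose extent cannot be
resolved on all six channels, or that touch a noisy segment, are marked
invalid and every sequence containing them is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

FS = 250.0
SEQUENCE_LENGTHS = (1, 5, 10, 20, 30, 50)

# systolic/diastolic acceptance ranges, mmHg (inclusive)
SYS_RANGE = (80.0, 220.0)
DIA_RANGE = (40.0, 120.0)

_MATCH_MAX_S = 0.500   # pulse valley must follow its R peak by 0..500 ms


@dataclass
class Beat:
    index: int
    r_peak: int
    ecg_extent: tuple          # (start, end), shared by all 4 leads
    spo2_extent: tuple
    abp_extent: tuple
    lead_fid: list             # per-lead dict of fiducials
    spo2_fid: dict             # valley/peak/min/max
    abp_fid: dict
    valid: bool = True

    @property
    def systolic(self) -> float:
        return self.abp_fid["max"]

    @property
    def diastolic(self) -> float:
        return self.abp_fid["min"]


@dataclass
class BeatSequence:
    beats: list
    subject_id: str = ""
    gold_systolic: float = np.nan
    gold_diastolic: float = np.nan
    rejected: bool = False

    def __post_init__(self):
        idx = [b.index for b in self.beats]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise InvalidInputError("sequence beats must be contiguous")
        if any(not b.valid for b in self.beats):
            raise InvalidInputError("sequence contains invalid beats")

    @property
    def L(self) -> int:
        return len(self.beats)

    @property
    def beat_indices(self) -> range:
        return range(self.beats[0].index, self.beats[0].index + len(self.beats))


def _match_pulse(r_peaks: np.ndarray, valleys: np.ndarray):
    """Match each ECG beat to the pulse beat whose valley follows its R
    peak within (0, 500 ms]; returns per-beat valley index or -1."""
    out = np.full(len(r_peaks), -1, dtype=int)
    max_lag = int(_MATCH_MAX_S * FS)
    for i, r in enumerate(r_peaks):
        after = np.where((valleys > r) & (valleys <= r + max_lag))[0]
        if len(after):
            out[i] = after[0]
    return out


def assemble_beats(ecg_fiducials: list, spo2_fiducials, abp_fiducials,
                   clean_mask: np.ndarray | None = None) -> list:
    """Build cross-channel beats from per-lead ECG fiducials plus SpO2 and
    ABP pulse fiducials.

    The first delineated beat has no prior T end and is therefore never
    valid.  ``clean_mask`` is a per-sample boolean; any beat whose extent
    touches a noisy sample on any channel is invalidated.
    """
    if len(ecg_fiducials) != 4:
        raise InvalidInputError("expected fiducials for 4 ECG leads")
    ref = ecg_fiducials[0]
    if ref.n_beats < 2:
        return []

    tol = int(0.060 * FS)
    n_ref = ref.n_beats
    # match every lead's beats to the reference lead's R peaks
    lead_rows = []
    for fid in ecg_fiducials:
        rows = np.full(n_ref, -1, dtype=int)
        for i, r in enumerate(ref.r_peak):
            j = np.argmin(np.abs(fid.r_peak - r)) if fid.n_beats else -1
            if j >= 0 and abs(int(fid.r_peak[j]) - int(r)) <= tol:
                rows[i] = j
        lead_rows.append(rows)

    spo2_map = _match_pulse(ref.r_peak, spo2_fiducials.valley) \
        if spo2_fiducials.n_beats else np.full(n_ref, -1)
    abp_map = _match_pulse(ref.r_peak, abp_fiducials.valley) \
        if abp_fiducials.n_beats else np.full(n_ref, -1)

    beats = []
    for k in range(n_ref):
        valid = all(rows[k] >= 0 for rows in lead_rows)
        valid &= k > 0 and all(rows[k - 1] >= 0 for rows in lead_rows)
        valid &= spo2_map[k] >= 0 and abp_map[k] >= 0
        # pulse beat needs a closing valley
        valid &= valid and spo2_map[k] < spo2_fiducials.n_beats
        valid &= valid and abp_map[k] < abp_fiducials.n_beats

        if not valid:
            beats.append(Beat(k, int(ref.r_peak[k]), (0, 0), (0, 0), (0, 0),
                              [], {}, {}, valid=False))
            continue

        # consensus extent: previous/current T end averaged across leads
        prev_t = int(np.median([ecg_fiducials[li].t_end[lead_rows[li][k - 1]]
                                for li in range(4)]))
        cur_t = int(np.median([ecg_fiducials[li].t_end[lead_rows[li][k]]
                               for li in range(4)]))
        lead_fid = []
        for li in range(4):
            f = ecg_fiducials[li]
            j = lead_rows[li][k]
            jp = lead_rows[li][k - 1]
            lead_fid.append({
                "r": int(f.r_peak[j]), "prev_r": int(f.r_peak[jp]),
                "qrs_onset": int(f.qrs_onset[j]),
                "qrs_offset": int(f.qrs_offset[j]), "t_peak": int(f.t_peak[j]),
                "t_end": int(f.t_end[j]), "t_amp": float(f.t_amplitude[j]),
            })
        sj = spo2_map[k]
        aj = abp_map[k]
        spo2_fid = {"valley": int(spo2_fiducials.valley[sj]),
                    "peak": int(spo2_fiducials.peak[sj]),
                    "min": float(spo2_fiducials.min_amp[sj]),
                    "max": float(spo2_fiducials.max_amp[sj])}
        abp_fid = {"valley": int(abp_fiducials.valley[aj]),
                   "peak": int(abp_fiducials.peak[aj]),
                   "min": float(abp_fiducials.min_amp[aj]),
                   "max": float(abp_fiducials.max_amp[aj])}
        spo2_ext = (int(spo2_fiducials.valley[sj]), int(spo2_fiducials.valley[sj + 1]))
        abp_ext = (int(abp_fiducials.valley[aj]), int(abp_fiducials.valley[aj + 1]))

        beat = Beat(k, int(ref.r_peak[k]), (prev_t, cur_t), spo2_ext, abp_ext,
                    lead_fid, spo2_fid, abp_fid, valid=True)
        if clean_mask is not None:
            for (a, b) in (beat.ecg_extent, beat.spo2_extent, beat.abp_extent):
                b = min(b, len(clean_mask))
                if a >= len(clean_mask) or not clean_mask[a:b].all():
                    beat.valid = False
                    break
        beats.append(beat)
    return beats


def build_sequences(beats: list, L: int, mode: str = "non_overlapping",
                    subject_id: str = "") -> list:
    """Pack valid contiguous beats into L-beat sequences.

    ``non_overlapping`` packs greedily left-to-right with stride L inside
    each contiguous run of valid beats; ``sliding`` uses stride 1 (the
    first beat index serves as the overlap bookkeeping key).
    """
    if L not in SEQUENCE_LENGTHS:
        raise InvalidInputError(f"L must be one of {SEQUENCE_LENGTHS}, got {L}")
    if mode not in ("non_overlapping", "sliding"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    runs = []
    cur = []
    for b in beats:
        if b.valid:
            cur.append(b)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    step = L if mode == "non_overlapping" else 1
    out = []
    for run in runs:
        for s in range(0, len(run) - L + 1, step):
            out.append(BeatSequence(run[s:s + L], subject_id=subject_id))
    return out


def gold_standard_bp(sequence: BeatSequence):
    """Median per-beat (max, min) ABP as the sequence gold standard.

    The sequence is rejected (not an error) when the medians fall outside
    systolic [80, 220] / diastolic [40, 120] mmHg; both labels and the
    flag are written onto the sequence and returned.
    """
    sys_v = float(np.median([b.systolic for b in sequence.beats]))
    dia_v = float(np.median([b.diastolic for b in sequence.beats]))
    sequence.gold_systolic = sys_v
    sequence.gold_diastolic = dia_v
    sequence.rejected = not (
        SYS_RANGE[0] <= sys_v <= SYS_RANGE[1]
        and DIA_RANGE[0] <= dia_v <= DIA_RANGE[1]
    )
    return (sys_v, dia_v), sequence.rejected
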