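"""Waveform record container and CSV / WFDB-style input-output.

A record bundles six synchronized channels — four ECG leads (mV), one
SpO2 plethysmographic channel (%) and one intra-arterial ABP channel
(mmHg) — together with the sampling rate and subject demographics.
All sample indexing in this package is 0-based with half-open
``[start, end)`` extents.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import resample_poly

from .errors import FormatError, InvalidRecordError, ParseError

TARGET_FS = 250.0

#: Default lead labels: three limb leads + one precordial lead.  The
#: analysis only distinguishes limb vs precordial; labels are metadata.
DEFAULT_ECG_LEADS = ("I", "II", "III", "V")

GENDER_CATEGORIES = ("female", "male", "missing")
RACE_CATEGORIES = ("Asian", "Black", "Hispanic", "White", "missing")


@dataclass(frozen=True)
class SubjectInfo:
    """Demographics attached to a record. Missing values use NaN/"missing"."""

    age: float = float("nan")
    bmi: float = float("nan")
    gender: str = "missing"
    race: str = "missing"

    def __post_init__(self):
        if self.gender not in GENDER_CATEGORIES:
            raise InvalidRecordError(f"gender must be one of {GENDER_CATEGORIES}, got {self.gender!r}")
        if self.race not in RACE_CATEGORIES:
            raise InvalidRecordError(f"race must be one of {RACE_CATEGORIES}, got {self.race!r}")
        if np.isfinite(self.age) and self.age < 0:
            raise InvalidRecordError(f"age must be >= 0, got {self.age}")
        if np.isfinite(self.bmi) and self.bmi <= 0:
            raise InvalidRecordError(f"bmi must be > 0, got {self.bmi}")


@dataclass
class WaveformRecord:
    """Six synchronized channels plus metadata.

    ``ecg`` has shape (4, n); ``spo2`` and ``abp`` have shape (n,).
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    spo2: np.ndarray
    abp: np.ndarray
    ecg_leads: tuple = DEFAULT_ECG_LEADS
    scale_factors: np.ndarray | None = None
    subject: SubjectInfo = field(default_factory=SubjectInfo)
    paced: bool = False

    def __post_init__(self):
        self.ecg = np.atleast_2d(np.asarray(self.ecg, dtype=float))
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.fs <= 0:
            raise InvalidRecordError(f"sampling rate must be positive, got {self.fs}")
        if self.ecg.shape[0] != 4:
            raise FormatError(f"expected 4 ECG leads, got {self.ecg.shape[0]}")
        n = self.ecg.shape[1]
        if n == 0:
            raise InvalidRecordError("channels must be non-empty")
        if self.spo2.shape != (n,) or self.abp.shape != (n,):
            raise InvalidRecordError(
                f"channel length mismatch: ecg {n}, spo2 {self.spo2.shape}, abp {self.abp.shape}"
            )
        if len(self.ecg_leads) != 4:
            raise FormatError("ecg_leads must name exactly 4 leads")

    @property
    def n_samples(self) -> int:
        return self.ecg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> dict:
        """All six channels keyed by canonical name (ecg_<lead>, spo2, abp)."""
        out = {f"ecg_{lab}": self.ecg[i] for i, lab in enumerate(self.ecg_leads)}
        out["spo2"] = self.spo2
        out["abp"] = self.abp
        return out

    def channel_kinds(self) -> dict:
        kinds = {f"ecg_{lab}": "ecg" for lab in self.ecg_leads}
        kinds["spo2"] = "spo2"
        kinds["abp"] = "abp"
        return kinds


def _meta_lines(record: WaveformRecord) -> list:
    meta = {
        "subject_id": record.subject_id,
        "fs": record.fs,
        "ecg_leads": list(record.ecg_leads),
        "paced": record.paced,
        "age": None if not np.isfinite(record.subject.age) else record.subject.age,
        "bmi": None if not np.isfinite(record.subject.bmi) else record.subject.bmi,
        "gender": record.subject.gender,
        "race": record.subject.race,
    }
    return ["# " + json.dumps(meta)]


def write_waveform_record(record: WaveformRecord, path) -> None:
    """Write a record as a labeled CSV with a JSON metadata comment line."""
    cols = record.channels()
    header = ",".join(cols)
    data = np.column_stack(list(cols.values()))
    with open(path, "w") as fh:
        for line in _meta_lines(record):
            fh.write(line + "\n")
        fh.write(header + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.10g")


def read_waveform_record(path, format: str = "csv", scale_factors=None) -> WaveformRecord:
    """Read a waveform record.

    ``format='csv'`` expects one header row with channel labels
    (``ecg_<lead>`` x4, ``spo2``, ``abp``) optionally preceded by a
    ``# {json}`` metadata line.  ``format='wfdb-style'`` delegates to the
    ``wfdb`` package when importable.  Device scale factors, when given,
    are applied multiplicatively per channel at read time.
    """
    if format == "wfdb-style":
        return _read_wfdb(path, scale_factors)
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")

    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# ").strip())
            except json.JSONDecodeError as exc:
                raise ParseError(f"bad metadata line in {path}: {exc}") from exc
            header = fh.readline()
        else:
            header = first
        labels = [c.strip() for c in header.strip().split(",")]
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ParseError(f"non-numeric samples in {path}: {exc}") from exc

    if data.shape[1] != len(labels):
        raise FormatError(f"{path}: {len(labels)} labels but {data.shape[1]} columns")
    cols = {lab: data[:, i] for i, lab in enumerate(labels)}

    ecg_labels = [lab for lab in labels if lab.lower().startswith("ecg")]
    if len(ecg_labels) != 4 or "spo2" not in cols or "abp" not in cols:
        raise FormatError(
            f"{path}: need 4 ECG channels + spo2 + abp, found {labels}"
        )

    if scale_factors is not None:
        sf = np.asarray(scale_factors, dtype=float)
        if sf.shape != (6,):
            raise FormatError("scale_factors must have 6 entries")
        for lab, s in zip(ecg_labels + ["spo2", "abp"], sf):
            cols[lab] = cols[lab] * s

    subject = SubjectInfo(
        age=meta.get("age") if meta.get("age") is not None else float("nan"),
        bmi=meta.get("bmi") if meta.get("bmi") is not None else float("nan"),
        gender=meta.get("gender", "missing"),
        race=meta.get("race", "missing"),
    )
    leads = tuple(lab.split("_", 1)[1] if "_" in lab else lab for lab in ecg_labels)
    return WaveformRecord(
        subject_id=str(meta.get("subject_id", "unknown")),
        fs=float(meta.get("fs", TARGET_FS)),
        ecg=np.stack([cols[lab] for lab in ecg_labels]),
        spo2=cols["spo2"],
        abp=cols["abp"],
        ecg_leads=leads,
        scale_factors=None if scale_factors is None else np.asarray(scale_factors, float),
        subject=subject,
        paced=bool(meta.get("paced", False)),
    )


def _read_wfdb(path, scale_factors):
    try:
        import wfdb  # noqa: F401
    except ImportError as exc:  # pragma: no cover - wfdb optional
        raise FormatError("wfdb-style input requires the optional 'wfdb' package") from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    labels = [s.lower() for s in rec.sig_name]  # pragma: no cover
    ecg_idx = [i for i, s in enumerate(labels) if "ecg" in s or s in ("i", "ii", "iii", "v")]  # pragma: no cover
    spo2_idx = [i for i, s in enumerate(labels) if "pleth" in s or "spo2" in s]  # pragma: no cover
    abp_idx = [i for i, s in enumerate(labels) if "abp" in s or "art" in s]  # pragma: no cover
    if len(ecg_idx) != 4 or not spo2_idx or not abp_idx:  # pragma: no cover
        raise FormatError("wfdb record does not expose 4 ECG + SpO2 + ABP channels")
    sig = rec.p_signal.T  # pragma: no cover
    return WaveformRecord(  # pragma: no cover
        subject_id=rec.record_name,
        fs=float(rec.fs),
        ecg=sig[ecg_idx],
        spo2=sig[spo2_idx[0]],
        abp=sig[abp_idx[0]],
        ecg_leads=tuple(rec.sig_name[i] for i in ecg_idx),
    )


def resample_to_250(record: WaveformRecord) -> WaveformRecord:
    """Resample all channels to 250 Hz; identity when fs is already 250.

    240 Hz input uses exact 25/24 polyphase resampling; other rates use
    the nearest rational approximation and emit a warning.
    """
    if record.fs <= 0:
        raise InvalidRecordError(f"sampling rate must be positive, got {record.fs}")
    if record.fs == TARGET_FS:
        return record
    if record.fs == 240.0:
        up, down = 25, 24
    else:
        warnings.warn(
            f"unexpected sampling rate {record.fs} Hz; resampling to 250 Hz anyway",
            stacklevel=2,
        )
        from fractions import Fraction

        frac = Fraction(TARGET_FS / record.fs).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator

    def _rs(x):
        return resample_poly(x, up, down)

    return replace(
        record,
        fs=TARGET_FS,
        ecg=np.stack([_rs(ch) for ch in record.ecg]),
        spo2=_rs(record.spo2),
        abp=_rs(record.abp),
    )
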