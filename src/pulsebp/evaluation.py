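"""Agreement statistics and device-standard grading of BP estimates.

"MAE +- X" throughout means the mean and the standard deviation of the
absolute errors.  Bland-Altman limits are mean +- 1.96 SD of the signed
differences.  The BHS ladder grades cumulative error percentages within
5/10/15 mmHg; the AAMI criterion requires |mean error| <= 5 mmHg and an
error SD <= 8 mmHg.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

SYS_BIN_EDGES = np.arange(80, 230, 10)
DIA_BIN_EDGES = np.arange(40, 130, 10)


@dataclass
class AgreementReport:
    n: int
    mae: float
    sd_ae: float
    mean_error: float
    loa_low: float
    loa_high: float
    pearson_r: float   # NaN when truth (or estimate) is constant

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class GradeReport:
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    bhs_grade: str
    aami_pass: bool
    mean_error: float
    sd_error: float


def agreement_report(estimates, truth) -> AgreementReport:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise InvalidInputError("estimates and truth must have equal length")
    if len(est) < 2:
        raise InvalidInputError("need at least 2 pairs")
    err = est - tru
    ae = np.abs(err)
    me = float(err.mean())
    sd = float(err.std(ddof=1))
    if np.ptp(tru) == 0 or np.ptp(est) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(est, tru)[0, 1])
    return AgreementReport(
        n=len(est),
        mae=float(ae.mean()),
        sd_ae=float(ae.std(ddof=1)),
        mean_error=me,
        loa_low=me - 1.96 * sd,
        loa_high=me + 1.96 * sd,
        pearson_r=r,
    )


def standards_grade(errors) -> GradeReport:
    err = np.asarray(errors, dtype=float)
    if len(err) < 1:
        raise InvalidInputError("need at least 1 error")
    ae = np.abs(err)
    pcts = tuple(100.0 * np.mean(ae <= t) for t in (5.0, 10.0, 15.0))
    grade = "D"
    for g, req in BHS_THRESHOLDS.items():
        if all(p >= q for p, q in zip(pcts, req)):
            grade = g
            break
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    aami = abs(float(err.mean())) <= 5.0 and sd <= 8.0
    return GradeReport(
        pct_within_5=pcts[0], pct_within_10=pcts[1], pct_within_15=pcts[2],
        bhs_grade=grade, aami_pass=bool(aami),
        mean_error=float(err.mean()), sd_error=sd,
    )


def stratified_report(estimates, truth, strata) -> pd.DataFrame:
    """One AgreementReport per stratum label; empty strata are simply
    absent, counts are reported per row."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    strata = np.asarray(strata)
    rows = []
    for label in pd.unique(strata):
        mask = strata == label
        if mask.sum() < 2:
            rows.append({"stratum": label, "n": int(mask.sum())})
            continue
        rep = agreement_report(est[mask], tru[mask])
        rows.append({"stratum": label, **rep.as_dict()})
    return pd.DataFrame(rows)


def bp_bins(truth, target: str = "systolic") -> np.ndarray:
    """10-mmHg stratum labels over the accepted BP range."""
    edges = SYS_BIN_EDGES if target == "systolic" else DIA_BIN_EDGES
    idx = np.clip(np.digitize(truth, edges) - 1, 0, len(edges) - 2)
    return np.array([f"{edges[i]}-{edges[i + 1]}" for i in idx])


def tracking_lag(estimated, truth, window: int = 20, max_lag: int = 10):
    """Modal argmax lag of windowed cross-correlation (lags -max..+max).

    Returns ``(lag, confident)``; ties in the mode are broken toward 0,
    and confidence is low when no lag wins a third of the windows or the
    winning correlations are weak.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or len(est) < 2 * window:
        raise InvalidInputError(f"series must be equal length >= {2 * window}")
    lags = []
    weak = 0
    for s in range(0, len(est) - window + 1, window):
        e = est[s:s + window]
        best = (-np.inf, 0)
        for lag in range(-max_lag, max_lag + 1):
            # positive lag: the estimate trails the truth by `lag` samples
            lo = s - lag
            hi = lo + window
            if lo < 0 or hi > len(tru):
                continue
            t = tru[lo:hi]
            if np.ptp(e) == 0 or np.ptp(t) == 0:
                continue
            c = np.corrcoef(e, t)[0, 1]
            if c > best[0] or (c == best[0] and abs(lag) < abs(best[1])):
                best = (c, lag)
        if np.isfinite(best[0]):
            lags.append(best[1])
            if best[0] < 0.5:
                weak += 1
    if not lags:
        return 0, False
    counts = Counter(lags)
    top = max(counts.values())
    modal = min((lag for lag, c in counts.items() if c == top), key=abs)
    confident = top >= max(2, len(lags) / 3) and weak <= len(lags) / 2
    return int(modal), bool(confident)
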