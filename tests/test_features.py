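"""Feature formulas checked against independent brute-force transcriptions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsebp.errors import InvalidInputError
from pulsebp.features import (
    DEFAULT_EXCLUDED,
    FEATURE_NAMES,
    amplitude_entropy,
    ar_coefficients,
    assemble_feature_vector,
    autocorr_feature,
    ecg_beat_features,
    encode_demographics,
    fractal_dimension,
    hjorth_params,
    kaiser_teager_energy,
    select_features,
    spectral_entropy,
    timing_features,
)
from pulsebp.records import SubjectInfo


# --- brute-force oracles (naive loops, no vectorization) -------------------

def brute_mobility_complexity(x):
    n = len(x)
    s0 = math.sqrt(sum(v * v for v in x) / n)
    d = [x[j + 1] - x[j] for j in range(n - 1)]
    s1 = math.sqrt(sum(v * v for v in d) / (n - 1))
    s2 = math.sqrt(sum((d[j + 1] - d[j]) ** 2 for j in range(n - 2)) / (n - 2))
    return s1 / s0, s2


def brute_entropy(x, m):
    lo, hi = min(x), max(x)
    width = (hi - lo) / m
    counts = [0] * m
    for v in x:
        b = min(int((v - lo) / width), m - 1) if width > 0 else 0
        counts[b] += 1
    total = len(x)
    return sum((c / total) * math.log(total / c) for c in counts if c > 0)


def brute_kte(s):
    return [s[i] ** 2 - s[i + 1] * s[i - 1] for i in range(1, len(s) - 1)]


def brute_autocorr(x, lag):
    num = sum(x[i] * x[i + lag] for i in range(len(x) - lag))
    den = sum(v * v for v in x)
    return num / den


def brute_yule_walker(x, order):
    x = [v - sum(x) / len(x) for v in x]
    n = len(x)
    r = [sum(x[i] * x[i + k] for i in range(n - k)) / n for k in range(order + 1)]
    R = [[r[abs(i - j)] for j in range(order)] for i in range(order)]
    return np.linalg.solve(np.array(R), np.array(r[1:]))


class TestHjorth:
    def test_ramp(self):
        mob, comp = hjorth_params([0, 1, 2, 3])
        assert mob == pytest.approx(1 / math.sqrt(3.5))
        assert comp == pytest.approx(0.0)

    def test_alternating(self):
        mob, comp = hjorth_params([1, -1, 1, -1])
        assert mob == pytest.approx(2.0)

    def test_constant(self):
        mob, comp = hjorth_params([3.0, 3.0, 3.0, 3.0])
        assert mob == 0.0 and comp == 0.0

    def test_all_zero_flagged_missing(self):
        mob, _ = hjorth_params([0.0, 0.0, 0.0])
        assert np.isnan(mob)

    def test_brute_force_100_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(0, rng.uniform(0.1, 10), rng.integers(10, 200))
            mob, comp = hjorth_params(x)
            bm, bc = brute_mobility_complexity(list(x))
            assert mob == pytest.approx(bm, rel=1e-10)
            assert comp == pytest.approx(bc, rel=1e-10)

    @given(st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=30, deadline=None)
    def test_mobility_scale_invariant(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 64)
        assert hjorth_params(x)[0] == pytest.approx(hjorth_params(c * x)[0],
                                                    rel=1e-9)


class TestEntropy:
    def test_single_bin_zero(self):
        assert amplitude_entropy(np.full(64, 5.0)) == 0.0

    def test_uniform_four_bins(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 16) + 0.01
        x[0] = 0.0  # pin the range
        assert amplitude_entropy(x, m=4) == pytest.approx(math.log(4), rel=0.01)

    def test_two_bins_half_half(self):
        x = np.array([0.0] * 16 + [1.0] * 16)
        assert amplitude_entropy(x, m=2) == pytest.approx(math.log(2))

    def test_brute_force_100_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(40, 300))
            assert amplitude_entropy(x) == pytest.approx(
                brute_entropy(list(x), 32), rel=1e-10)

    def test_scale_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        assert amplitude_entropy(x) == pytest.approx(amplitude_entropy(5 * x))


class TestFractalDimension:
    def test_line_near_one(self):
        assert fractal_dimension(np.linspace(0, 10, 500)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_above_1_5(self):
        x = np.random.default_rng(3).normal(0, 1, 1000)
        assert fractal_dimension(x) > 1.5

    def test_constant_one(self):
        assert fractal_dimension(np.full(100, 2.0)) == 1.0

    def test_short_input_missing(self):
        assert np.isnan(fractal_dimension(np.arange(10)))


class TestAutocorr:
    def test_lag_zero_is_one(self):
        x = np.random.default_rng(4).normal(0, 1, 50)
        assert autocorr_feature(x, lag=0) == pytest.approx(1.0)

    def test_sinusoid_at_period(self):
        n, p = 1000, 50
        x = np.sin(2 * np.pi * np.arange(n) / p)
        v = autocorr_feature(x, lag=p)
        assert v == pytest.approx(1 - p / n, abs=0.01)

    def test_white_noise_small_at_center(self):
        n = 400
        x = np.random.default_rng(5).normal(0, 1, n)
        assert abs(autocorr_feature(x)) < 3 / np.sqrt(n)

    def test_zero_energy_missing(self):
        assert np.isnan(autocorr_feature(np.zeros(10)))

    def test_brute_force_100_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(10, 100))
            lag = len(x) // 2
            assert autocorr_feature(x) == pytest.approx(
                brute_autocorr(list(x), lag), rel=1e-10)


class TestKte:
    def test_constant_zero(self):
        np.testing.assert_allclose(kaiser_teager_energy(np.full(20, 3.0)), 0.0)

    def test_ramp_identity(self):
        # s_i = i: i^2 - (i+1)(i-1) = 1 for every interior sample
        np.testing.assert_allclose(kaiser_teager_energy(np.arange(20.0)), 1.0)

    def test_brute_force_100_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = rng.normal(0, 2, rng.integers(5, 80))
            np.testing.assert_allclose(kaiser_teager_energy(s),
                                       brute_kte(list(s)), rtol=1e-10, atol=1e-12)

    def test_quadratic_scaling(self):
        s = np.random.default_rng(8).normal(0, 1, 30)
        np.testing.assert_allclose(kaiser_teager_energy(3 * s),
                                   9 * kaiser_teager_energy(s), rtol=1e-9)


class TestArCoefficients:
    def test_recovery_mean_over_seeds(self):
        true = np.array([0.5, -0.3, 0.2, -0.1, 0.05])
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1250
            x = np.zeros(n + 100)
            for t in range(5, n + 100):
                x[t] = true @ x[t - 5:t][::-1] + rng.normal()
            fits.append(ar_coefficients(x[100:]))
        err = np.abs(np.mean(fits, axis=0) - true)
        assert np.all(err < 0.05)

    def test_matches_brute_yule_walker(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.normal(0, 1, 200)
            np.testing.assert_allclose(ar_coefficients(x),
                                       brute_yule_walker(list(x), 5), rtol=1e-8)

    def test_constant_flagged_missing(self):
        assert np.all(np.isnan(ar_coefficients(np.full(100, 2.0))))


class TestSpectralEntropy:
    def test_sinusoid_lower_than_noise(self):
        t = np.arange(1000) / 250.0
        tone = np.sin(2 * np.pi * 1.3 * t)
        noise = np.random.default_rng(10).normal(0, 1, 1000)
        assert spectral_entropy(tone) < spectral_entropy(noise)

    def test_constant_zero(self):
        assert spectral_entropy(np.full(100, 7.0)) == 0.0


class TestDemographics:
    def test_female_white(self):
        f = encode_demographics(SubjectInfo(age=40, bmi=22, gender="female",
                                            race="White"))
        assert f["gender_code"] == 1
        assert [f["race_white"], f["race_hispanic"], f["race_asian"],
                f["race_black"]] == [1, 0, 0, 0]

    def test_male_black(self):
        f = encode_demographics(SubjectInfo(gender="male", race="Black"))
        assert f["gender_code"] == 2
        assert [f["race_white"], f["race_hispanic"], f["race_asian"],
                f["race_black"]] == [0, 0, 0, 1]

    def test_missing_all_zero(self):
        f = encode_demographics(SubjectInfo())
        assert np.isnan(f["gender_code"])
        assert f["race_white"] + f["race_hispanic"] + f["race_asian"] + \
            f["race_black"] == 0


class TestSchema:
    def test_48_features(self):
        assert len(FEATURE_NAMES) == 48
        assert len(set(FEATURE_NAMES)) == 48

    def test_default_selection_34(self):
        report = select_features()
        assert len(report.selected) == 34
        assert len(report.excluded) == 14
        assert set(report.selected) | set(report.excluded) == set(FEATURE_NAMES)

    def test_block_counts(self):
        per_lead = [n for n in FEATURE_NAMES if n[-2:] in
                    ("_1", "_2", "_3", "_4")]
        assert len(per_lead) == 28
        assert len(DEFAULT_EXCLUDED) == 4 + 1 + 4 + 5

    def test_importance_ranking_mode(self):
        imp = {n: float(i) for i, n in enumerate(FEATURE_NAMES)}
        report = select_features(importance=imp, n_keep=10)
        assert len(report.selected) == 10
        assert set(report.selected) == set(FEATURE_NAMES[-10:])


@pytest.fixture(scope="module")
def sequences(clean_record):
    from pulsebp.beats import assemble_beats, build_sequences
    from pulsebp.pipeline import delineate_record

    rec, truth = clean_record
    ecg_fids, spo2_fid, abp_fid = delineate_record(rec)
    beats = assemble_beats(ecg_fids, spo2_fid, abp_fid)
    return rec, truth, build_sequences(beats, 5)


class TestSequenceFeatures:
    def test_vector_has_48_entries(self, sequences):
        rec, _, seqs = sequences
        vec = assemble_feature_vector(seqs[0], rec)
        assert tuple(vec) == FEATURE_NAMES

    def test_deterministic(self, sequences):
        rec, _, seqs = sequences
        a = assemble_feature_vector(seqs[1], rec)
        b = assemble_feature_vector(seqs[1], rec)
        assert a == b

    def test_heart_rate_close_to_programmed(self, sequences):
        rec, _, seqs = sequences
        hr, pat, t2 = timing_features(seqs[0])
        assert 55 < hr < 70
        assert pat > 0

    def test_pat_matches_truth(self, sequences):
        rec, truth, seqs = sequences
        for seq in seqs[:5]:
            _, pat, _ = timing_features(seq)
            idx = [b.index for b in seq.beats]
            true_pat = np.mean(truth.pat_ms[idx] / 1000.0)
            assert pat == pytest.approx(true_pat, abs=0.008)

    def test_qtc_bazett(self, sequences):
        rec, _, seqs = sequences
        qtc, t_amp = ecg_beat_features(seqs[0], 0)
        # simulator QT ~ 0.25*sqrt(RR)+0.04+2*sigma_t; sanity band
        assert 0.3 < qtc < 0.55
        assert t_amp > 0

    def test_rr_one_second_identity(self):
        # Bazett with RR = 1 s leaves QT unchanged
        beats = []
        from pulsebp.beats import Beat
        for i in range(3):
            beats.append(Beat(
                index=i, r_peak=250 * i + 100,
                ecg_extent=(250 * i, 250 * i + 250),
                spo2_extent=(0, 1), abp_extent=(0, 1),
                lead_fid=[{"r": 250 * i + 100, "prev_r": 250 * (i - 1) + 100,
                           "qrs_onset": 250 * i + 60,
                           "qrs_offset": 0, "t_peak": 0,
                           "t_end": 250 * i + 60 + int([0.38, 0.40, 0.42][i] * 250),
                           "t_amp": 0.2}] * 4,
                spo2_fid={"valley": 0, "peak": 250 * i + 150, "min": 0, "max": 1},
                abp_fid={"valley": 0, "peak": 0, "min": 80, "max": 120}))
        from pulsebp.beats import BeatSequence
        seq = BeatSequence(beats)
        qtc, _ = ecg_beat_features(seq, 0)
        assert qtc == pytest.approx(0.40, abs=0.01)

    def test_missing_propagates_per_lead(self, sequences):
        rec, _, seqs = sequences
        seq = seqs[0]
        for f in (b.lead_fid[2] for b in seq.beats):
            f["prev_r"] = f["r"]  # degenerate RR -> lead-3 qtc missing
        vec = assemble_feature_vector(seq, rec)
        assert np.isnan(vec["qtc_3"])
        assert not np.isnan(vec["qtc_1"])


def test_hjorth_too_short_rejected():
    with pytest.raises(InvalidInputError):
        hjorth_params([1.0, 2.0])


def test_entropy_shorter_than_bins_rejected():
    with pytest.raises(InvalidInputError):
        amplitude_entropy(np.arange(10), m=32)
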