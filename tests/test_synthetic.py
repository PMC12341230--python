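"""Generator contracts: determinism, spectral ground truth, injected structure."""
import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from afdas.datatypes import AFIntervalSet
from afdas.synthetic import (CohortConfig, DropoutSpec, EffectSizes, RRProfile,
                             draw_labels, inject_af_episodes, inject_ectopy,
                             insert_monitoring_gaps, sample_clinical_features,
                             simulate_cohort, simulate_rr_series,
                             synthesize_ecg)


@pytest.fixture(scope="module")
def quiet_profile():
    return RRProfile(mean_rr_ms=800.0, lf_amp=0.0, hf_amp=0.0, noise_frac=0.0)


class TestSimulateRR:
    def test_zero_noise_limit_gives_constant_rr(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 1.0, seed=0)
        assert abs(s.n_beats - 4500) <= 1
        rr = np.diff(s.times)
        assert np.allclose(rr, 0.8, atol=1e-9)

    def test_hf_only_modulation_concentrates_power_in_hf_band(self):
        p = RRProfile(mean_rr_ms=800.0, lf_amp=0.0, hf_amp=0.05,
                      noise_frac=0.0, hf_freq_hz=0.25)
        s = simulate_rr_series(p, 1.0, seed=3)
        t, rr = s.times[1:], np.diff(s.times)
        grid = np.arange(t[0], t[-1], 0.25)
        x = np.interp(grid, t, rr)
        f, psd = periodogram(x, fs=4.0)
        hf = psd[(f >= 0.15) & (f <= 0.4)].sum()
        tp = psd[(f >= 0.003) & (f <= 0.4)].sum()
        assert hf / tp > 0.8

    def test_same_seed_reproduces_beat_times(self):
        p = RRProfile()
        a = simulate_rr_series(p, 0.5, seed=42)
        b = simulate_rr_series(p, 0.5, seed=42)
        assert np.array_equal(a.times, b.times)

    def test_strictly_increasing_times(self):
        s = simulate_rr_series(RRProfile(noise_frac=0.1), 0.5, seed=1)
        assert np.all(np.diff(s.times) > 0)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            RRProfile(mean_rr_ms=-10.0)


class TestInjectEctopy:
    def test_zero_rates_identity(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 0.2, seed=0)
        out = inject_ectopy(s, 0.0, 0.0, seed=1)
        assert np.array_equal(out.times, s.times)
        assert np.array_equal(out.labels, s.labels)

    def test_sves_count_is_poisson_with_requested_mean(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 1.0, seed=0)
        counts = [np.sum(inject_ectopy(s, 36.0, 0.0, seed=k).labels == "S")
                  for k in range(200)]
        # Monte-Carlo mean of a Poisson(36) over 200 seeds
        assert abs(np.mean(counts) - 36.0) < 3 * np.sqrt(36.0 / 200)

    def test_labels_confined_to_nsv_and_order_preserved(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 0.5, seed=0)
        out = inject_ectopy(s, 60.0, 30.0, seed=5)
        assert set(np.unique(out.labels)) <= {"N", "S", "V"}
        assert np.all(np.diff(out.times) > 0)
        assert out.n_beats == s.n_beats


class TestInjectAF:
    def test_zero_rate_identity(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 0.5, seed=0)
        out, af = inject_af_episodes(s, 0.0, seed=1)
        assert af.n == 0
        assert np.array_equal(out.times, s.times)

    def test_rr_inside_af_serially_uncorrelated(self):
        s = simulate_rr_series(RRProfile(), 2.0, seed=2)
        out, af = inject_af_episodes(s, 2.0, seed=7, mean_duration_s=120.0)
        assert af.n >= 1
        rs = []
        for a, b in af.intervals:
            inside = (out.times >= a) & (out.times < b)
            rr = np.diff(out.times[inside])
            if rr.size > 30:
                r = np.corrcoef(rr[:-1], rr[1:])[0, 1]
                rs.append(r)
        assert rs, "no AF interval long enough to test"
        assert np.all(np.abs(rs) < 0.25)
        assert abs(np.mean(rs)) < 0.15

    def test_every_interval_at_least_30s(self):
        s = simulate_rr_series(RRProfile(), 3.0, seed=4)
        _, af = inject_af_episodes(s, 1.5, seed=9)
        if af.n:
            assert np.all(af.intervals[:, 1] - af.intervals[:, 0] >= 30.0)

    def test_minimum_duration_enforced(self):
        s = simulate_rr_series(RRProfile(), 0.5, seed=0)
        with pytest.raises(ValueError):
            inject_af_episodes(s, 1.0, seed=0, min_duration_s=10.0)


class TestMonitoringGaps:
    def test_zero_dropout_identity(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 0.5, seed=0)
        out = insert_monitoring_gaps(s, DropoutSpec(gaps_per_hour=0.0), seed=1)
        assert np.array_equal(out.times, s.times)

    def test_mean_gap_time_matches_spec(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 2.0, seed=0)
        spec = DropoutSpec(gaps_per_hour=1.0, mean_gap_s=120.0, sigma_log=0.4)
        totals = []
        for k in range(120):
            out = insert_monitoring_gaps(s, spec, seed=k)
            totals.append(sum(e - a for a, e in out.gaps))
        # expectation ~ rate * hours * mean length = 2 * 120 = 240 s (merging
        # of overlapping gaps biases slightly low)
        assert 150.0 < np.mean(totals) < 300.0

    def test_gap_removal_is_bookkept(self, quiet_profile):
        s = simulate_rr_series(quiet_profile, 1.0, seed=0)
        out = insert_monitoring_gaps(s, DropoutSpec(gaps_per_hour=2.0), seed=3)
        removed = s.n_beats - out.n_beats
        in_gap = np.zeros(s.n_beats, dtype=bool)
        for a, e in out.gaps:
            in_gap |= (s.times >= a) & (s.times < e)
        assert removed == int(in_gap.sum())


class TestClinical:
    def test_group_age_contrast_matches_configured_shift(self):
        es = EffectSizes()
        ages = {lab: [sample_clinical_features(lab, es, seed=1000 * j + i).age
                      for i in range(500)]
                for j, lab in enumerate(["no_af", "ndaf"])}
        diff = np.mean(ages["ndaf"]) - np.mean(ages["no_af"])
        assert abs(diff - es.age_shift_years) < 2.0

    def test_null_age_effect(self):
        es = EffectSizes(age_shift_years=0.0)
        a = [sample_clinical_features("no_af", es, seed=i).age for i in range(400)]
        b = [sample_clinical_features("ndaf", es, seed=9000 + i).age for i in range(400)]
        assert abs(np.mean(a) - np.mean(b)) < 2.5

    def test_range_constraints(self):
        es = EffectSizes()
        for i in range(200):
            c = sample_clinical_features("ndaf", es, seed=i)
            assert c.gfr > 0
            assert 0 <= c.nihss <= 42
            assert isinstance(c.nihss, int)


class TestECG:
    def test_r_peak_recovery(self):
        s = simulate_rr_series(RRProfile(), 0.15, seed=6)
        ecg = synthesize_ecg(s, AFIntervalSet.empty(), seed=0,
                             noise_sd_mv=0.005)
        peaks, _ = find_peaks(ecg.samples, height=0.5, distance=int(0.3 * 500))
        peak_t = peaks / 500.0
        hits = sum(np.min(np.abs(peak_t - bt)) <= 0.02 for bt in s.times)
        assert hits / s.n_beats >= 0.99

    def test_record_length(self):
        s = simulate_rr_series(RRProfile(), 0.05, seed=0)
        ecg = synthesize_ecg(s, AFIntervalSet.empty(), seed=0)
        assert ecg.samples.size == int(np.ceil((s.times[-1] + 1.0) * 500))

    def test_p_wave_absent_inside_af(self):
        s = simulate_rr_series(RRProfile(mean_rr_ms=800, lf_amp=0, hf_amp=0,
                                         noise_frac=0), 0.1, seed=0)
        af = AFIntervalSet(np.array([[100.0, 200.0]]))
        clean = synthesize_ecg(s, AFIntervalSet.empty(), seed=0,
                               noise_sd_mv=0.0, fibrillatory_amp_mv=0.0)
        suppressed = synthesize_ecg(s, af, seed=0, noise_sd_mv=0.0,
                                    fibrillatory_amp_mv=0.0)
        # pick a beat well inside the AF span and sample at the P-wave offset
        bt = s.times[(s.times > 110) & (s.times < 190)][0]
        idx = int(round((bt - 0.170) * 500))
        window = slice(idx - 5, idx + 6)
        assert np.max(clean.samples[window]) > 0.08
        assert np.max(np.abs(suppressed.samples[window])) < 0.02


class TestCohort:
    def test_full_determinism(self):
        cfg = CohortConfig(n_patients=4, monitoring_hours=0.5, seed=77)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for pa, pb in zip(a, b):
            assert pa.label == pb.label
            assert np.array_equal(pa.beat_stream.times, pb.beat_stream.times)
            assert np.array_equal(pa.af_intervals.intervals,
                                  pb.af_intervals.intervals)
            assert pa.clinical.as_dict() == pb.clinical.as_dict()

    def test_prevalence_within_binomial_interval(self):
        cfg = CohortConfig(n_patients=1000, af_prevalence=0.06, seed=5)
        labels = draw_labels(cfg)
        k = int(np.sum(labels == "ndaf"))
        # binomial 99% interval around n*p
        sd = np.sqrt(1000 * 0.06 * 0.94)
        assert abs(k - 60) < 2.58 * sd

    def test_label_parameter_consistency(self, small_cohort):
        _, patients = small_cohort
        hf = {"af": [], "ctl": []}
        for p in patients:
            key = "af" if p.label != "no_af" else "ctl"
            hf[key].append(p.ground_truth_params["profile"].hf_amp)
        ratio = np.mean(hf["af"]) / np.mean(hf["ctl"])
        assert 1.2 < ratio < 2.0  # configured rmssd_ratio 1.5 up to sampling noise

    def test_no_af_patient_has_no_alarms(self, small_cohort):
        _, patients = small_cohort
        for p in patients:
            if p.label == "no_af":
                assert p.af_intervals.n == 0

    def test_intervals_nonoverlapping_within_record(self, small_cohort):
        cfg, patients = small_cohort
        for p in patients:
            iv = p.af_intervals.intervals
            if iv.size:
                assert np.all(iv[1:, 0] >= iv[:-1, 1])
                assert iv[0, 0] >= 0
                assert iv[-1, 1] <= cfg.monitoring_hours * 3600 + 1
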