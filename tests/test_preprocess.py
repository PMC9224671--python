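"""Filters, ectopic detection/interpolation, and the threshold delineator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriosync import (CohortConfig, delineate, detect_ectopics,
                       generate_patient, interpolate_ectopics, patient_seeds,
                       remove_baseline_wander, remove_powerline,
                       render_waveforms)

FS = 1000.0


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestPowerlineNotch:
    def test_rejects_line_frequency_by_20db(self):
        t = np.arange(int(5 * FS)) / FS
        x = 0.1 * np.sin(2 * np.pi * 50.0 * t)
        y = remove_powerline(x, FS, 50.0)
        core = y[500:-500]  # exclude filter edge transients
        assert np.max(np.abs(core)) <= 0.01

    def test_preserves_broadband_energy(self, rng):
        x = rng.normal(0, 0.1, int(10 * FS))
        y = remove_powerline(x, FS, 50.0)
        assert abs(_rms(y) - _rms(x)) / _rms(x) < 0.10

    def test_zero_in_zero_out(self):
        y = remove_powerline(np.zeros(2000), FS, 50.0)
        np.testing.assert_allclose(y, 0.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            remove_powerline(np.zeros(1000), 90.0, 50.0)

    def test_linearity(self, rng):
        x = rng.normal(0, 0.1, 4000)
        np.testing.assert_allclose(remove_powerline(3.0 * x, FS),
                                   3.0 * remove_powerline(x, FS), atol=1e-9)


class TestBaselineWander:
    def test_attenuates_slow_drift(self):
        t = np.arange(int(30 * FS)) / FS
        x = 0.5 * np.sin(2 * np.pi * 0.1 * t)
        y = remove_baseline_wander(x, FS, cutoff=0.5)
        assert np.max(np.abs(y[5000:-5000])) <= 0.05

    def test_removes_dc_offset(self):
        y = remove_baseline_wander(np.full(5000, 1.0), FS)
        assert abs(y.mean()) < 1e-6

    def test_preserves_5hz_within_1db(self):
        t = np.arange(int(10 * FS)) / FS
        x = 0.2 * np.sin(2 * np.pi * 5.0 * t)
        y = remove_baseline_wander(x, FS, cutoff=0.5)
        ratio = _rms(y[1000:-1000]) / _rms(x[1000:-1000])
        assert 10 ** (-1 / 20) <= ratio <= 10 ** (1 / 20)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            remove_baseline_wander(np.zeros(1000), FS, cutoff=600.0)

    def test_wander_does_not_break_duration_recovery(self):
        """End to end: P-wave train + heavy wander, durations within 2 ms."""
        onsets = np.arange(500, 20000, 800)
        ann = np.array([[o, o + 60, o + 120] for o in onsets])
        clean = render_waveforms(ann, np.full(len(ann), 0.2), "surface", FS,
                                 21000.0)
        t = np.arange(len(clean)) / FS
        wander = 0.4 * np.sin(2 * np.pi * 0.3 * t)
        filtered = remove_baseline_wander(clean + wander, FS)
        d_clean = delineate(clean, FS, ann[:, 1])
        d_filt = delineate(filtered, FS, ann[:, 1])
        dur_clean = d_clean[:, 2] - d_clean[:, 0]
        dur_filt = d_filt[:, 2] - d_filt[:, 0]
        # interior beats: the first/last carry filtfilt boundary transients
        assert np.max(np.abs(dur_clean - dur_filt)[2:-2]) <= 2


class TestEctopicDetection:
    @staticmethod
    def _ann_from_peaks(peaks_ms):
        peaks = np.asarray(peaks_ms, dtype=np.int64)
        return np.column_stack([peaks - 60, peaks, peaks + 60])

    def test_regular_rhythm_unflagged(self):
        ann = self._ann_from_peaks(np.arange(20) * 800 + 500)
        assert not detect_ectopics(ann, FS).any()

    def test_single_short_interval_flagged(self):
        peaks = list(np.arange(20) * 800 + 500)
        peaks[10] -= 300  # preceding interval 500 among 800s
        ann = self._ann_from_peaks(peaks)
        flags = detect_ectopics(ann, FS)
        assert flags[10]
        assert flags.sum() == 1  # compensatory pause not double-counted

    def test_requires_twelve_beats(self):
        ann = self._ann_from_peaks(np.arange(5) * 800 + 500)
        with pytest.raises(ValueError):
            detect_ectopics(ann, FS)

    def test_simulation_sensitivity_and_specificity(self):
        """At 4% prevalence with >=30% shortening the detector recovers the
        generator's flags; fiducial jitter at delineation scale (5 ms)."""
        cfg = CohortConfig(n_patients=1, n_beats=300, ectopic_rate=0.04,
                           channel_ibi_jitter_sd=5.0, seed=0)
        tp = fn = fp = tn = 0
        for ps in range(10):
            surf, _, truth = generate_patient(cfg, "pre", ps, render=False)
            flags = detect_ectopics(surf.annotations, FS)
            t = truth.ectopic_flags
            tp += int((flags & t).sum())
            fn += int((~flags & t).sum())
            fp += int((flags & ~t).sum())
            tn += int((~flags & ~t).sum())
        assert tp / (tp + fn) >= 0.95
        assert fp / (fp + tn) <= 0.01


class TestInterpolation:
    def test_midpoint(self):
        out = interpolate_ectopics([100.0, 999.0, 120.0],
                                   [False, True, False])
        np.testing.assert_allclose(out, [100.0, 110.0, 120.0])

    def test_no_flags_identity(self):
        x = [5.0, 6.0, 7.0]
        np.testing.assert_array_equal(interpolate_ectopics(x, [False] * 3), x)

    def test_two_adjacent_flags_thirds(self):
        out = interpolate_ectopics([100.0, 0.0, 0.0, 130.0],
                                   [False, True, True, False])
        np.testing.assert_allclose(out, [100.0, 110.0, 120.0, 130.0])

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            interpolate_ectopics([1.0, 2.0], [True, True])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
           st.data())
    @settings(max_examples=30, deadline=None)
    def test_unflagged_entries_never_change(self, values, data):
        flags = data.draw(st.lists(st.booleans(), min_size=len(values),
                                   max_size=len(values)))
        if all(flags):
            flags[0] = False
        out = interpolate_ectopics(values, flags)
        keep = ~np.asarray(flags)
        np.testing.assert_array_equal(np.asarray(values)[keep], out[keep])


class TestDelineate:
    def test_noise_free_pwave_within_4ms(self):
        ann = np.array([[1000, 1060, 1120]])
        x = render_waveforms(ann, np.array([0.2]), "surface", FS, 2500.0)
        d = delineate(x, FS, [1060])
        assert abs((d[0, 2] - d[0, 0]) - 120) <= 4

    def test_noise_free_law(self):
        ann = np.array([[1000, 1060, 1090]])
        x = render_waveforms(ann, np.array([0.5]), "cs", FS, 2500.0)
        d = delineate(x, FS, [1060], "cs")
        assert abs((d[0, 2] - d[0, 0]) - 90) <= 8

    def test_translation_invariance(self):
        ann = np.array([[1000, 1060, 1120], [2500, 2560, 2620]])
        x = render_waveforms(ann, np.array([0.2, 0.2]), "surface", FS, 4000.0)
        d = delineate(x, FS, ann[:, 1])
        assert (d[0, 2] - d[0, 0]) == (d[1, 2] - d[1, 0])

    def test_min_separation_enforced(self):
        with pytest.raises(ValueError, match="200 ms"):
            delineate(np.zeros(2000), FS, [500, 600])

    def test_flat_window_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = delineate(np.zeros(3000), FS, [1500])
        assert len(out) == 0

    def test_snr20_cohort_median_error(self):
        """Median absolute duration error <= 8 ms at 20 dB SNR."""
        rng = np.random.default_rng(0)
        ann = np.array([[o, o + 60, o + 120]
                        for o in range(500, 40000, 800)])
        clean = render_waveforms(ann, np.full(len(ann), 0.2), "surface", FS,
                                 41000.0)
        sig_rms = _rms(clean[clean != 0])
        noisy = clean + rng.normal(0, 0.1 * sig_rms, len(clean))
        d = delineate(noisy, FS, ann[:, 1])
        errs = np.abs((d[:, 2] - d[:, 0]) - 120)
        assert np.median(errs) <= 8

    def test_output_satisfies_annotation_invariants(self, one_patient):
        surf, _, _ = one_patient
        x = remove_baseline_wander(remove_powerline(surf.samples, FS), FS)
        d = delineate(x, FS, surf.annotations[:, 1])
        assert np.all(d[:, 0] < d[:, 1]) and np.all(d[:, 1] < d[:, 2])
        assert np.all(d[1:, 0] > d[:-1, 2])
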