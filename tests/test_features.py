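"""Morphology features, rate-variability summaries and HR adjustment."""

import numpy as np
import pandas as pd
import pytest

from atriosync import (amplitude_features, arv_summary, compute_ibi, duration,
                       extract_features, generate_ibi_series, generate_patient,
                       hra_adjust, positive_area, slope_rate)

FS = 1000.0


class TestDuration:
    def test_definition(self):
        assert duration((1000, 1060, 1120), FS) == 120.0

    def test_single_sample(self):
        assert duration((0, 1, 1), FS) == pytest.approx(1.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            duration((10, 10, 10), FS)

    def test_ground_truth_round_trip(self, one_patient):
        surf, _, truth = one_patient
        feats = extract_features(surf, ectopic_flags=np.zeros(
            surf.n_activations, dtype=bool))
        d_ann = (surf.annotations[:, 2] - surf.annotations[:, 0]) / FS * 1000
        np.testing.assert_allclose(feats.table["duration"], d_ann, atol=1.0)


class TestAmplitude:
    def test_three_sample_closed_form(self):
        amp, pp, rms = amplitude_features(np.array([0.0, 0.2, 0.0]),
                                          (0, 1, 2))
        assert amp == pytest.approx(0.2)
        assert pp == pytest.approx(0.2)
        assert rms == pytest.approx(np.sqrt(0.04 / 3))

    def test_biphasic_pp_exceeds_ampmax(self):
        amp, pp, _ = amplitude_features(np.array([-0.1, 0.2]), (0, 1, 1))
        assert pp == pytest.approx(0.3)
        assert amp == pytest.approx(0.2)

    def test_nonnegative_pwave_ampmax_equals_pp(self, one_patient):
        """Positive lead-II P-waves: maximum and peak-to-peak amplitudes
        concur (rendered without noise)."""
        from atriosync import render_waveforms

        ann = np.array([[500, 560, 620]])
        x = render_waveforms(ann, np.array([0.15]), "surface", FS, 1500.0)
        amp, pp, _ = amplitude_features(x, ann[0])
        assert amp == pytest.approx(pp)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            amplitude_features(np.zeros(10), (8, 9, 5))


class TestPositiveArea:
    def test_rectangle(self):
        x = np.zeros(200)
        x[50:151] = 0.1  # 0.1 mV for 100 ms inclusive
        assert positive_area(x, (50, 100, 150), FS) == pytest.approx(
            10.0, abs=0.1)

    def test_all_negative_clipped_to_zero(self):
        assert positive_area(-np.ones(50), (0, 25, 49), FS) == 0.0

    def test_triangle(self):
        x = np.concatenate([np.linspace(0, 0.2, 61),
                            np.linspace(0.2, 0, 61)[1:]])
        area = positive_area(x, (0, 60, 120), FS)
        assert area == pytest.approx(12.0, abs=0.1)


class TestSlopeRate:
    def test_linear_ramp_constant_slope(self):
        x = np.linspace(0.0, 0.2, 101)  # 0 -> 0.2 mV over 100 ms
        ann = (0, 100, 100)
        assert slope_rate(x, ann, FS, "max") == pytest.approx(0.002)
        assert slope_rate(x, ann, FS, "20%") == pytest.approx(0.002)

    def test_positive_for_monophasic_hump(self):
        from atriosync import render_waveforms

        ann = np.array([[500, 560, 620]])
        x = render_waveforms(ann, np.array([0.2]), "surface", FS, 1500.0)
        assert slope_rate(x, ann[0], FS, "max") > 0

    def test_negative_early_slope_for_downward_law(self):
        from atriosync import render_waveforms

        ann = np.array([[500, 560, 590]])
        x = render_waveforms(ann, np.array([0.5]), "cs", FS, 1500.0)
        assert slope_rate(x, ann[0], FS, "5%") < 0

    def test_degenerate_rounding_advances_one_sample(self):
        x = np.linspace(0.0, 0.1, 11)
        val = slope_rate(x, (0, 5, 10), FS, "5%")  # 5% of 10 rounds to 0
        assert np.isfinite(val) and val > 0


class TestIbi:
    def test_definition(self):
        ann = np.array([[0, 0, 1], [700, 800, 900], [1500, 1650, 1700]])
        out = compute_ibi(ann, FS)
        assert np.isnan(out[0])
        np.testing.assert_allclose(out[1:], [800.0, 850.0])

    def test_constant_spacing(self):
        ann = np.column_stack([np.arange(5) * 800,
                               np.arange(5) * 800 + 60,
                               np.arange(5) * 800 + 120])
        out = compute_ibi(ann, FS)
        np.testing.assert_allclose(out[1:], 800.0)

    def test_non_increasing_rejected(self):
        ann = np.array([[0, 100, 150], [120, 90, 200]])
        with pytest.raises(ValueError):
            compute_ibi(ann, FS)


class TestHra:
    def test_scaling_factor_arithmetic(self):
        table = pd.DataFrame({"duration": [120.0], "posar": [10.0],
                              "smax": [0.002], "s5": [0.001],
                              "s10": [0.001], "s20": [0.001],
                              "ibi": [800.0]})
        out = hra_adjust(table)
        assert out.loc[0, "sf"] == pytest.approx(1.25)
        assert out.loc[0, "hra_duration"] == pytest.approx(150.0)
        assert out.loc[0, "hra_posar"] == pytest.approx(12.5)
        assert out.loc[0, "hra_smax"] == pytest.approx(0.0016)

    def test_identity_at_1000ms_cycle(self):
        table = pd.DataFrame({"duration": [120.0], "posar": [10.0],
                              "smax": [0.002], "ibi": [1000.0]})
        out = hra_adjust(table)
        assert out.loc[0, "hra_duration"] == table.loc[0, "duration"]
        assert out.loc[0, "hra_smax"] == table.loc[0, "smax"]

    def test_first_beat_undefined(self):
        table = pd.DataFrame({"duration": [120.0, 118.0],
                              "ibi": [np.nan, 800.0]})
        out = hra_adjust(table)
        assert np.isnan(out.loc[0, "hra_duration"])
        assert np.isfinite(out.loc[1, "hra_duration"])

    def test_invariant_to_global_time_rescaling(self):
        """hra_duration is unchanged when every duration and IBI is
        multiplied by the same factor — the core of the adjustment."""
        rng = np.random.default_rng(0)
        dur = rng.uniform(80, 160, 50)
        ibi = rng.uniform(600, 1000, 50)
        t1 = hra_adjust(pd.DataFrame({"duration": dur, "ibi": ibi}))
        t2 = hra_adjust(pd.DataFrame({"duration": 1.3 * dur,
                                      "ibi": 1.3 * ibi}))
        np.testing.assert_allclose(t1["hra_duration"], t2["hra_duration"])


class TestArv:
    def test_constant_intervals(self):
        out = arv_summary([800.0, 800.0, 800.0])
        assert out.sdnn == out.varnn == out.rmssd == 0.0

    def test_closed_form(self):
        out = arv_summary([790.0, 800.0, 810.0])
        assert out.sdnn == pytest.approx(10.0)
        assert out.varnn == pytest.approx(100.0)
        assert out.rmssd == pytest.approx(10.0)

    def test_varnn_is_sdnn_squared(self, rng):
        out = arv_summary(rng.uniform(600, 1000, 200))
        assert out.varnn == pytest.approx(out.sdnn ** 2, rel=1e-12)

    def test_rmssd_shift_invariant(self, rng):
        ivl = rng.uniform(600, 1000, 100)
        assert arv_summary(ivl).rmssd == pytest.approx(
            arv_summary(ivl + 123.0).rmssd)

    def test_ar1_series_sdnn_matches_generator(self):
        ivl = generate_ibi_series(3000, 800.0, 50.0, 0.6, seed=9)
        assert abs(arv_summary(ivl).sdnn - 50.0) < 5.0

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            arv_summary([800.0, 810.0])


class TestExtractFeatures:
    def test_fiducial_only_mode(self, small_config):
        from atriosync import patient_seeds

        seeds = patient_seeds(small_config)
        surf, _, _ = generate_patient(small_config, "pre", int(seeds[0]),
                                      render=False)
        feats = extract_features(surf)
        assert "duration" in feats.table and "hra_duration" in feats.table
        assert "ampmax" not in feats.table

    def test_full_mode_has_all_features(self, one_patient):
        surf, _, _ = one_patient
        feats = extract_features(surf)
        for col in ("duration", "ampmax", "pp", "rms", "posar", "s5", "s10",
                    "s20", "smax", "ibi", "sf", "hra_duration", "hra_posar",
                    "hra_smax"):
            assert col in feats.table

    def test_ectopic_interpolation_smooths_flagged_beats(self):
        from atriosync import CohortConfig

        cfg = CohortConfig(n_patients=1, n_beats=300, ectopic_rate=0.04,
                           seed=1)
        surf, _, truth = generate_patient(cfg, "pre", 3, render=False)
        assert truth.ectopic_flags.any()
        raw = extract_features(surf, ectopic_flags=np.zeros(
            surf.n_activations, dtype=bool)).table
        fixed = extract_features(surf).table
        i = int(np.flatnonzero(truth.ectopic_flags)[0])
        # the flagged beat's shortened cycle is replaced by a local estimate
        assert fixed.loc[i, "ibi"] > raw.loc[i, "ibi"]
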