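"""Feature extractor correctness: analytic signals, moment-formula
oracles, Parseval normalisation, layout and naming contracts."""

import dataclasses

import numpy as np
import pytest

from nirspd.exceptions import SpecError
from nirspd.features import (
    FeatureMatrix,
    N_FEATURES_PER_BAND,
    Signal,
    Spectrum,
    extract_feature_matrix,
    feature_columns,
    parse_feature_name,
    power_spectrum,
    spectral_features,
    temporal_features,
)
from nirspd.synthetic_data import CohortSpec, generate_cohort

FS = 25.0


def _sine(freq, duration=360.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestTemporalFeatures:
    def test_pure_sine_interval_features(self):
        f = temporal_features(Signal(_sine(1.0), FS))
        assert f["zc_interval"] == pytest.approx(0.5, abs=1 / FS)
        assert f["zc_to_peak"] == pytest.approx(0.25, abs=1 / FS)

    def test_three_sample_moment_oracle(self):
        x = np.array([-3.0, 1.0, 2.0])
        f = temporal_features(Signal(x, 1.0))
        assert f["max_abs"] == 3.0
        assert f["mean"] == 0.0
        # direct evaluation of the population moment formulas
        m2 = np.mean(x**2)
        m3 = np.mean(x**3)
        assert f["variance"] == pytest.approx(m2)
        assert f["skewness"] == pytest.approx(m3 / m2**1.5)
        assert f["skewness"] != 0.0

    def test_negation_symmetry(self):
        x = _sine(0.5, duration=20.0) + 0.3 * _sine(2.2, duration=20.0, phase=1.0)
        x += 0.1  # offset so the mean is informative
        a = temporal_features(Signal(x, FS))
        b = temporal_features(Signal(-x, FS))
        for inv in ("max_abs", "variance", "zc_interval", "zc_to_peak"):
            assert a[inv] == pytest.approx(b[inv], rel=1e-12)
        assert a["mean"] == pytest.approx(-b["mean"])
        assert a["skewness"] == pytest.approx(-b["skewness"])

    def test_constant_signal_conventions(self):
        f = temporal_features(Signal(np.full(100, 2.5), 10.0))
        assert f["variance"] == 0.0 and f["skewness"] == 0.0
        assert f["zc_interval"] == 10.0  # duration sentinel
        assert f["zc_to_peak"] == 10.0

    def test_circular_shift_invariance(self):
        x = _sine(0.5, duration=40.0)
        a = temporal_features(Signal(x, FS))
        b = temporal_features(Signal(np.roll(x, 250), FS))
        for key in ("max_abs", "mean", "variance", "skewness"):
            assert abs(a[key] - b[key]) < 1e-9
        for key in ("zc_interval", "zc_to_peak"):
            assert abs(a[key] - b[key]) <= 1 / FS


class TestPowerSpectrum:
    def test_sine_has_single_dominant_bin(self):
        sp = power_spectrum(Signal(_sine(2.0), FS))
        assert sp.freqs_hz[np.argmax(sp.magnitude)] == pytest.approx(2.0, abs=FS / 9000)

    def test_amplitude_ordering(self):
        x = _sine(0.1, amp=2.0) + _sine(1.0, amp=1.0)
        sp = power_spectrum(Signal(x, FS))
        i_low = np.argmin(np.abs(sp.freqs_hz - 0.1))
        i_high = np.argmin(np.abs(sp.freqs_hz - 1.0))
        assert sp.magnitude[i_low] > sp.magnitude[i_high]

    @pytest.mark.parametrize("n", [1000, 1001])  # even and odd lengths
    def test_parseval(self, n):
        x = np.random.default_rng(3).normal(size=n)
        sp = power_spectrum(Signal(x, FS))
        e_time = np.sum((x - x.mean()) ** 2)
        assert abs((sp.magnitude**2).sum() - e_time) / e_time < 1e-9

    def test_dc_excluded_and_increasing(self):
        sp = power_spectrum(Signal(_sine(1.0, duration=10.0), FS))
        assert sp.freqs_hz[0] > 0
        assert np.all(np.diff(sp.freqs_hz) > 0)


class TestSpectralFeatures:
    def test_four_bin_oracle(self):
        sp = Spectrum(np.array([0.5, 1.0, 1.5, 2.0]), np.array([0.0, 0.0, 4.0, 0.0]))
        f = spectral_features(sp)
        assert f["energy"] == 16.0
        assert f["dominant_freq"] == 1.5
        assert f["mean"] == 1.0
        m = np.array([0.0, 0.0, 4.0, 0.0])
        d = m - 1.0
        m2 = np.mean(d**2)
        assert f["variance"] == pytest.approx(m2)
        assert f["skewness"] == pytest.approx(np.mean(d**3) / m2**1.5)
        assert f["kurtosis"] == pytest.approx(np.mean(d**4) / m2**2)

    def test_scale_homogeneity(self):
        sp = power_spectrum(Signal(_sine(0.3, duration=30.0), FS))
        f1 = spectral_features(sp)
        f2 = spectral_features(Spectrum(sp.freqs_hz, 3.0 * sp.magnitude))
        assert f2["energy"] == pytest.approx(9.0 * f1["energy"])
        assert f2["dominant_freq"] == f1["dominant_freq"]
        assert f2["skewness"] == pytest.approx(f1["skewness"])

    def test_all_zero_spectrum_conventions(self):
        f = spectral_features(Spectrum(np.array([1.0, 2.0]), np.zeros(2)))
        assert f["mean"] == f["variance"] == f["skewness"] == f["kurtosis"] == 0.0
        assert np.isnan(f["dominant_freq"])


class TestExtractFeatureMatrix:
    def test_default_layout_has_792_columns(self, tiny_spec):
        # 22 channels x 3 bands x 12 features
        assert len(feature_columns(22)) == 792
        fm = extract_feature_matrix(generate_cohort(tiny_spec))
        assert fm.n_features == tiny_spec.n_channels * 3 * N_FEATURES_PER_BAND

    def test_one_channel_cohort_has_36_columns(self):
        spec = CohortSpec(n_per_class=2, n_long_channels=1, n_short_channels=0,
                          duration_s=20.0, effect_channels=(0,))
        fm = extract_feature_matrix(generate_cohort(spec))
        assert fm.n_features == 36

    def test_names_unique_and_parseable(self):
        cols = feature_columns(22)
        assert len(set(cols)) == 792
        for col in cols[::37]:
            ch, band, domain, name = parse_feature_name(col)
            assert 0 <= ch < 22 and band in ("hbo", "hbr", "hbt")
            assert domain in ("t", "s")

    def test_pruned_channel_is_median_filled(self, tiny_cohort):
        import copy

        cohort = copy.deepcopy(tiny_cohort)
        cohort.records[0].channel_meta[1] = dataclasses.replace(
            cohort.records[0].channel_meta[1], retained=False
        )
        fm_full = extract_feature_matrix(tiny_cohort)
        fm = extract_feature_matrix(cohort)
        assert fm.provenance["median_filled"] == [(cohort.records[0].subject_id, 1)]
        col = "ch02_hbo_t_variance"
        others = fm_full.data[col].iloc[1:]
        assert fm.data[col].iloc[0] == pytest.approx(np.median(others))

    def test_inconsistent_layout_rejected(self, tiny_cohort):
        import copy

        cohort = copy.deepcopy(tiny_cohort)
        cohort.records[0].data = cohort.records[0].data[:, :3, :]
        cohort.records[0].channel_meta = cohort.records[0].channel_meta[:3]
        with pytest.raises(SpecError, match="layout"):
            extract_feature_matrix(cohort)

    def test_csv_round_trip(self, tiny_cohort, tmp_path):
        fm = extract_feature_matrix(tiny_cohort)
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        assert back.feature_names == fm.feature_names
        assert np.array_equal(back.y, fm.y)
        assert np.allclose(back.values, fm.values)


def test_effect_channels_show_larger_class_separation():
    """Planted channels' targeted features separate the classes more
    strongly (Cohen's d) than the same features on unaffected channels."""
    targeted = ("t_variance", "s_energy", "s_dominant_freq")
    d_eff, d_rest = [], []
    for seed in range(10):
        spec = CohortSpec(n_per_class=8, duration_s=60.0, effect_size=2.0,
                          effect_channels=(0, 1, 2, 3, 4), seed=seed)
        fm = extract_feature_matrix(generate_cohort(spec))
        y = fm.y
        for col in fm.feature_names:
            ch, band, domain, name = parse_feature_name(col)
            if f"{domain}_{name}" not in targeted or band != "hbo" or ch >= 20:
                continue
            v = fm.data[col].to_numpy()
            a, b = v[y == 1], v[y == 0]
            pooled = np.sqrt((a.var() + b.var()) / 2)
            d = abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
            (d_eff if ch in (0, 1, 2, 3, 4) else d_rest).append(d)
    assert np.mean(d_eff) > np.mean(d_rest)
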