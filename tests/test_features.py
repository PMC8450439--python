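import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import cwt_center_oracle
from sepsiskit.features import (
    WindowConfig,
    ricker_kernel,
    build_feature_matrix,
    cwt_features,
    extract_window,
    fft_features,
    impute_stream,
    statistical_features,
)

BASE = pd.Timestamp("2024-01-01 00:00:00", tz="UTC")


def minute_vitals(hours=30, patient="p1"):
    ts = pd.date_range(BASE, periods=hours * 60, freq="1min")
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"patient_id": patient, "timestamp": ts})
    for ch in ("hr", "rr", "spo2", "sbp", "dbp", "map"):
        df[ch] = rng.normal(80, 5, len(ts))
    return df


class TestExtractWindow:
    def test_interval_arithmetic(self):
        v = minute_vitals(hours=30)
        arrays = extract_window(v, BASE + pd.Timedelta(hours=20), WindowConfig())
        for arr in arrays.values():
            assert arr.shape == (3, 60)
        # window covers hours [5, 8) post-admission
        expected = v.set_index("timestamp")["hr"][
            BASE + pd.Timedelta(hours=5): BASE + pd.Timedelta(hours=8)
        ].to_numpy()[:180]
        np.testing.assert_array_equal(arrays["hr"].ravel(), expected)

    def test_right_open_boundary_excludes_horizon_sample(self):
        v = minute_vitals(hours=30)
        t_event = BASE + pd.Timedelta(hours=20)
        arrays = extract_window(v, t_event, WindowConfig())
        edge = v.set_index("timestamp").loc[t_event - pd.Timedelta(hours=12), "hr"]
        assert edge not in arrays["hr"][-1]

    def test_window_before_admission_rejected(self):
        v = minute_vitals(hours=30)
        with pytest.raises(ValueError, match="p1"):
            extract_window(v, BASE + pd.Timedelta(hours=14), WindowConfig())


class TestImpute:
    def test_locf_carries_previous_record(self):
        np.testing.assert_array_equal(
            impute_stream(np.array([1.0, np.nan, 3.0]), 80.0), [1.0, 1.0, 3.0]
        )

    def test_leading_gap_takes_population_median(self):
        np.testing.assert_array_equal(
            impute_stream(np.array([np.nan, np.nan]), 80.0), [80.0, 80.0]
        )

    def test_complete_input_identity(self):
        x = np.array([2.0, 4.0, 6.0])
        np.testing.assert_array_equal(impute_stream(x, 0.0), x)

    def test_nonfinite_median_rejected(self):
        with pytest.raises(ValueError):
            impute_stream(np.array([np.nan]), np.nan)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.none(), st.floats(-100, 100, allow_nan=False)),
            min_size=1,
            max_size=40,
        ),
        st.floats(-50, 50, allow_nan=False),
    )
    def test_idempotence(self, vals, med):
        x = np.array([np.nan if v is None else v for v in vals])
        once = impute_stream(x, med)
        np.testing.assert_array_equal(impute_stream(once, med), once)
        assert not np.isnan(once).any()


class TestStatisticalFeatures:
    def test_basic_aggregates(self):
        f = statistical_features(np.array([1.0, 2, 3, 4]))
        assert f["mean"] == 2.5 and f["sum"] == 10
        assert f["minimum"] == 1 and f["maximum"] == 4

    def test_moments_against_direct_computation(self):
        f = statistical_features(np.array([1.0, 2, 3, 4]))
        assert f["variance"] == pytest.approx(5.0 / 3.0, rel=1e-9)
        assert f["std"] == pytest.approx(np.sqrt(5.0 / 3.0), rel=1e-9)
        assert f["kurtosis"] == pytest.approx(-1.36, abs=1e-9)

    def test_constant_series_degenerate_moments(self):
        f = statistical_features(np.full(60, 5.0))
        assert f["std"] == 0 and f["variance"] == 0
        assert np.isnan(f["kurtosis"])

    def test_empty_input_all_null_length_zero(self):
        f = statistical_features(np.array([]), n_observed=0)
        assert f["length"] == 0
        assert all(np.isnan(f[k]) for k in f if k != "length")

    def test_length_counts_observed_samples(self):
        f = statistical_features(np.ones(60), n_observed=42)
        assert f["length"] == 42


class TestFftFeatures:
    def test_constant_series_dc_only(self):
        f = fft_features(np.full(60, 3.0), range(0, 97, 4))
        assert f[0] == pytest.approx(180.0)
        for k in range(4, 29, 4):
            assert f[k] == pytest.approx(0.0, abs=1e-9)

    def test_unit_impulse_flat_spectrum(self):
        f = fft_features(np.array([1.0, 0, 0, 0]), [0, 2])
        assert f[0] == pytest.approx(1.0)
        assert f[2] == pytest.approx(1.0)

    def test_beyond_one_sided_spectrum_is_null(self):
        f = fft_features(np.zeros(60) + 1, [96])
        assert np.isnan(f[96])


class TestCwtFeatures:
    def test_zero_series_zero_coefficients(self):
        f = cwt_features(np.zeros(60), range(2, 21, 2))
        assert all(v == 0 for v in f.values())

    def test_default_width_grid_size(self):
        f = cwt_features(np.random.default_rng(0).normal(size=60), WindowConfig().cwt_widths)
        assert len(f) == 10

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            cwt_features(np.ones(60), [0])

    def test_matches_bruteforce_convolution(self, rng):
        x = rng.normal(size=60)
        for w in (2, 10, 20):
            ours = cwt_features(x, [w])[w]
            assert ours == pytest.approx(cwt_center_oracle(list(x), w), rel=1e-9)

    def test_matches_pywavelets_shape_family(self, rng):
        """The per-width transform agrees with PyWavelets' Mexican-hat CWT up
        to its scale-dependent normalization (cross-library sanity check)."""
        pywt = pytest.importorskip("pywt")
        x = rng.normal(size=60)
        w = 4
        ours_full = np.convolve(x, ricker_kernel(40, w), mode="same")
        theirs, _ = pywt.cwt(x, [w], "mexh")
        corr = np.corrcoef(ours_full, theirs[0])[0, 1]
        assert corr > 0.99


class TestFeatureMatrix:
    def test_default_grid_column_count(self):
        cfg = WindowConfig()
        assert cfg.n_features == 774
        assert len(cfg.column_names()) == 774
        assert len(set(cfg.column_names())) == 774

    def test_all_null_columns_dropped_and_logged(self, small_cohort, small_labels):
        fm = build_feature_matrix(small_labels.labels, small_cohort.vitals)
        assert fm.X.shape[1] == 774 - len(fm.dropped_columns)
        # Fourier indices beyond n/2 = 30 of a 60-sample hour are structural nulls
        assert all("__fft__" in c for c in fm.dropped_columns)
        assert not fm.X.isna().any().any()

    def test_row_order_independence(self, small_cohort, small_labels):
        labels = small_labels.labels
        perm = labels.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = build_feature_matrix(labels, small_cohort.vitals)
        b = build_feature_matrix(perm, small_cohort.vitals)
        pd.testing.assert_frame_equal(a.X.sort_index(), b.X.sort_index())

    def test_translation_invariance(self):
        v = minute_vitals(hours=30)
        labels = pd.DataFrame(
            {"patient_id": ["p1"], "t_event": [BASE + pd.Timedelta(hours=20)],
             "is_case": [True]}
        )
        shift = pd.Timedelta(days=3)
        v2 = v.assign(timestamp=v.timestamp + shift)
        labels2 = labels.assign(t_event=labels.t_event + shift)
        a = build_feature_matrix(labels, v)
        b = build_feature_matrix(labels2, v2)
        np.testing.assert_allclose(a.X.to_numpy(), b.X.to_numpy(), rtol=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix(
                pd.DataFrame(columns=["patient_id", "t_event", "is_case"]),
                minute_vitals(),
            )

    def test_subwindow_grid_divisibility_enforced(self):
        with pytest.raises(ValueError):
            WindowConfig(window_h=3, subwindow_h=2).validate()
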