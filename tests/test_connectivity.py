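"""Denoising and connectivity-stage unit tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sysseg import (
    ConfoundSet,
    ROITimeSeries,
    correlation_matrix,
    denoise,
    detect_spikes,
    expand_confounds,
    fisher_z,
    highpass_filter,
    regress_confounds,
    summarize_roi,
    timeseries_to_connectivity,
)
from sysseg.connectivity import BASE_CONFOUND_COLUMNS, dct_drift_basis
from sysseg.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)


def make_confounds(rng, t, spike_frame=None):
    base = pd.DataFrame(
        rng.normal(scale=0.05, size=(t, 9)), columns=list(BASE_CONFOUND_COLUMNS)
    )
    if spike_frame is not None:
        base.iloc[spike_frame, :6] += 5.0
    return ConfoundSet(base)


class TestSummarizeRoi:
    def test_single_voxel_is_centered_series(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        out = summarize_roi(v[:, None])
        centered = v - v.mean()
        assert np.allclose(np.abs(np.corrcoef(out, centered)[0, 1]), 1.0)
        assert np.corrcoef(out, centered)[0, 1] > 0

    def test_duplicated_voxel_matches_single(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        one = summarize_roi(v[:, None])
        two = summarize_roi(np.column_stack([v, v]))
        assert np.allclose(np.corrcoef(one, two)[0, 1], 1.0)

    def test_recovers_planted_rank_one_signal(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=200)
        w = rng.uniform(0.5, 1.5, size=30)
        block = np.outer(s, w) + rng.normal(scale=0.05, size=(200, 30))
        out = summarize_roi(block)
        assert np.corrcoef(out, s)[0, 1] > 0.99

    def test_constant_block_raises(self):
        with pytest.raises(DegenerateInputError):
            summarize_roi(np.ones((20, 4)))


class TestExpandConfounds:
    def test_constant_column_derivative_zero_square_constant(self):
        base = pd.DataFrame({"c": np.full(10, 3.0)})
        out = expand_confounds(base)
        assert np.all(out["c_derivative1"] == 0.0)
        assert np.all(out["c_power2"] == 9.0)

    def test_backward_difference_with_leading_zero(self):
        base = pd.DataFrame({"c": [0.0, 1.0, 2.0, 3.0]})
        out = expand_confounds(base)
        assert list(out["c_derivative1"]) == [0.0, 1.0, 1.0, 1.0]
        assert list(out["c_derivative1_power2"]) == [0.0, 1.0, 1.0, 1.0]

    def test_thirty_six_columns_and_rank(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame(
            rng.normal(size=(100, 9)), columns=list(BASE_CONFOUND_COLUMNS)
        )
        out = expand_confounds(base)
        assert out.shape[1] == 36
        # independent linear-algebra check of the construction's rank
        assert np.linalg.matrix_rank(out.to_numpy()) == 36

    def test_missing_column_named_in_error(self):
        base = pd.DataFrame({"trans_x": np.zeros(5)})
        with pytest.raises(KeyError, match="csf"):
            ConfoundSet(base)


class TestDetectSpikes:
    def test_zero_motion_no_spikes(self):
        assert detect_spikes(np.zeros((50, 6))).size == 0

    def test_single_displaced_frame_flagged(self):
        rng = np.random.default_rng(4)
        params = rng.normal(scale=0.01, size=(100, 6))
        params[40] += 5.0  # ~50 score-SDs
        frames = detect_spikes(params, k=5.0)
        assert list(frames) == [40]

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        params = np.cumsum(rng.normal(scale=0.1, size=(200, 6)), axis=0)
        loose = set(detect_spikes(params, k=1.0))
        strict = set(detect_spikes(params, k=500.0))
        assert strict <= loose

    def test_bad_k_rejected(self):
        with pytest.raises(ValidationError):
            detect_spikes(np.zeros((50, 6)), k=0.0)


class TestHighpass:
    def _tone(self, freq, t=300, tr=2.0):
        time = np.arange(t) * tr
        return ROITimeSeries(np.sin(2 * np.pi * freq * time)[:, None], tr, ["r1"])

    def test_slow_tone_removed(self):
        ts = self._tone(0.005)
        out = highpass_filter(ts, cutoff=0.01)
        assert out.values.var() < 0.01 * ts.values.var()

    def test_fast_tone_preserved(self):
        ts = self._tone(0.05)
        out = highpass_filter(ts, cutoff=0.01)
        assert out.values.var() > 0.95 * ts.values.var()

    def test_projection_idempotent(self):
        rng = np.random.default_rng(6)
        raw = ROITimeSeries(rng.normal(size=(200, 3)), 2.0, ["a", "b", "c"])
        once = highpass_filter(raw, 0.01)
        twice = highpass_filter(once, 0.01)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            highpass_filter(self._tone(0.05), cutoff=0.5)


class TestRegressConfounds:
    def test_design_column_fully_removed(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=100)
        ts = ROITimeSeries(col[:, None], 1.0, ["r1"])
        out = regress_confounds(ts, col[:, None])
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_input_unchanged(self):
        t = np.arange(100, dtype=float)
        design = np.column_stack([np.ones(100)])
        sig = np.sin(2 * np.pi * t / 10)
        sig -= sig.mean()
        ts = ROITimeSeries(sig[:, None], 1.0, ["r1"])
        out = regress_confounds(ts, design)
        assert np.allclose(out.values[:, 0], sig, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        design = rng.normal(size=(200, 10))
        ts = ROITimeSeries(rng.normal(size=(200, 5)), 1.0, [f"r{i}" for i in range(5)])
        out = regress_confounds(ts, design)
        dots = np.abs(design.T @ out.values)
        norms = np.linalg.norm(design, axis=0)[:, None] * np.linalg.norm(out.values, axis=0)
        assert np.max(dots / norms) < 1e-8

    def test_planted_mixture_cleaned(self):
        rng = np.random.default_rng(9)
        signal = rng.normal(size=300)
        confound = rng.normal(size=300)
        mixed = signal + 0.5 * confound
        ts = ROITimeSeries(mixed[:, None], 1.0, ["r1"])
        out = regress_confounds(ts, np.column_stack([np.ones(300), confound]))
        r_before = np.corrcoef(mixed, signal)[0, 1]
        r_after = np.corrcoef(out.values[:, 0], signal)[0, 1]
        assert r_after > r_before

    def test_rank_deficient_design_warns(self):
        rng = np.random.default_rng(10)
        col = rng.normal(size=100)
        design = np.column_stack([col, col, rng.normal(size=100)])
        ts = ROITimeSeries(rng.normal(size=(100, 2)), 1.0, ["a", "b"])
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_confounds(ts, design)

    def test_too_few_timepoints_rejected(self):
        rng = np.random.default_rng(11)
        ts = ROITimeSeries(rng.normal(size=(10, 2)), 1.0, ["a", "b"])
        with pytest.raises(InsufficientDataError):
            regress_confounds(ts, rng.normal(size=(10, 12)))


class TestCorrelationAndFisher:
    def test_identical_and_negated_series(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=100)
        ts = ROITimeSeries(np.column_stack([v, v + 0.0, -v]), 1.0, ["a", "b", "c"])
        r = correlation_matrix(ts)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_known_population_correlation(self):
        rng = np.random.default_rng(13)
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=10000)
        r = correlation_matrix(ROITimeSeries(x, 1.0, ["a", "b"]))
        assert r[0, 1] == pytest.approx(0.3, abs=0.02)

    def test_zero_variance_roi_named(self):
        ts = ROITimeSeries(
            np.column_stack([np.ones(50), np.arange(50.0)]), 1.0, ["flat", "ramp"]
        )
        with pytest.raises(DegenerateInputError, match="flat"):
            correlation_matrix(ts)

    def test_fisher_z_reference_values(self):
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert fisher_z(r).z_values[0, 1] == 0.0
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert fisher_z(r).z_values[0, 1] == pytest.approx(np.arctanh(0.5))

    def test_white_noise_correction_is_near_identity(self):
        rng = np.random.default_rng(14)
        ts = ROITimeSeries(rng.normal(size=(1000, 4)), 1.0, list("abcd"))
        r = correlation_matrix(ts)
        plain = fisher_z(r).z_values
        corrected = fisher_z(r, ts_length=1000, autocorr_correction=True, timeseries=ts).z_values
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(corrected[off], plain[off], atol=0.02)

    def test_singular_edge_rejected(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateInputError):
            fisher_z(r)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-0.99, max_value=0.99), st.floats(min_value=1e-6, max_value=0.009))
    def test_fisher_z_strictly_increasing_and_odd(self, r, eps):
        def z_of(v):
            mat = np.array([[1.0, v], [v, 1.0]])
            return fisher_z(mat).z_values[0, 1]

        assert z_of(-r) == pytest.approx(-z_of(r), abs=1e-12)
        if r + eps < 1.0 and eps > 0:
            assert z_of(r + eps) > z_of(r)


class TestFullStage:
    def test_roi_permutation_equivariance(self):
        rng = np.random.default_rng(15)
        values = rng.normal(size=(200, 5))
        ids = [f"r{i}" for i in range(5)]
        conf = make_confounds(rng, 200)
        m = timeseries_to_connectivity(ROITimeSeries(values, 1.0, ids), conf)
        perm = [3, 0, 4, 1, 2]
        m_perm = timeseries_to_connectivity(
            ROITimeSeries(values[:, perm], 1.0, [ids[i] for i in perm]), conf
        )
        assert np.allclose(m.z_values[np.ix_(perm, perm)], m_perm.z_values, atol=1e-10)

    def test_bit_identical_reruns(self):
        rng = np.random.default_rng(16)
        values = rng.normal(size=(150, 4))
        conf = make_confounds(rng, 150)
        ts = ROITimeSeries(values, 1.0, list("abcd"))
        a = timeseries_to_connectivity(ts, conf)
        b = timeseries_to_connectivity(ts, conf)
        assert np.array_equal(a.z_values, b.z_values)

    def test_spike_columns_enter_design(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(150, 4))
        conf = make_confounds(rng, 150, spike_frame=70)
        ts = ROITimeSeries(values, 1.0, list("abcd"))
        # the spiked frame is absorbed: residual variance at that frame ~ 0
        resid = denoise(ts, conf)
        assert np.allclose(resid.values[70], 0.0, atol=1e-8)


def test_drift_basis_frequencies_span_cutoff():
    basis = dct_drift_basis(300, 2.0, 0.01)
    assert basis.shape == (300, 12)  # floor(2 * 0.01 * 600)
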