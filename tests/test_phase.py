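"""Preprocessing, Hilbert phases, coherence matrices, leading eigenvectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from leida import (
    ConfigurationError,
    DegenerateSignalError,
    ParcelTimeSeries,
    canonicalize_sign,
    eigenvector_series,
    instantaneous_phase,
    leading_eigenvector,
    phase_coherence,
    preprocess_series,
)


def _scan(data, tr=2.0):
    return ParcelTimeSeries(data=np.asarray(data, float), tr=tr)


class TestPreprocess:
    def test_constant_column_becomes_zero(self):
        ts = _scan(np.column_stack([np.full(60, 7.0), np.random.default_rng(0).normal(size=60)]))
        out = preprocess_series(ts, band=None)
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_linear_trend_removed(self):
        t = np.arange(60, dtype=float)
        ts = _scan(np.column_stack([3.0 + 0.5 * t, -2.0 - 0.1 * t]))
        out = preprocess_series(ts, band=None)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_passband_amplitude_preserved(self):
        # 0.04 Hz sits mid-band; interior excludes the ~100 s edge
        # transient of the 0.01 Hz high-pass edge
        t = np.arange(400) * 2.0
        x = np.cos(2 * np.pi * 0.04 * t)
        out = preprocess_series(_scan(np.column_stack([x, x]))).data[:, 0]
        interior = out[100:-100]
        assert 0.95 <= np.abs(interior).max() <= 1.05

    def test_stopband_attenuated(self):
        from scipy import signal as sps

        t = np.arange(400) * 2.0
        x = np.cos(2 * np.pi * 0.2 * t)
        out = preprocess_series(_scan(np.column_stack([x, x]))).data[:, 0]
        assert np.abs(out[100:-100]).max() <= 0.2  # >= 80% reduction
        # analytic cross-check of the designed response (squared: zero-phase)
        sos = sps.butter(2, (0.01, 0.08), btype="bandpass", fs=0.5, output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.2], fs=0.5)
        assert np.abs(h[0]) ** 2 <= 0.2

    def test_band_outside_nyquist_rejected(self):
        ts = _scan(np.random.default_rng(0).normal(size=(60, 3)))
        with pytest.raises(ConfigurationError):
            preprocess_series(ts, band=(0.01, 0.3))  # Nyquist = 0.25 Hz
        with pytest.raises(ConfigurationError):
            preprocess_series(ts, band=(0.08, 0.01))


class TestInstantaneousPhase:
    def test_cosine_phase_is_linear_in_time(self):
        f, tr, T = 0.04, 2.0, 200
        t = np.arange(T) * tr
        ts = _scan(np.column_stack([np.cos(2 * np.pi * f * t)] * 2), tr)
        theta = instantaneous_phase(ts)[:, 0]
        expected = np.angle(np.exp(1j * 2 * np.pi * f * t))
        err = np.abs(np.angle(np.exp(1j * (theta - expected))))
        assert err[20:-20].max() < 0.05
        assert (theta > -np.pi).all() and (theta <= np.pi).all()

    def test_sine_lags_cosine_by_quarter_cycle(self):
        f, tr, T = 0.04, 2.0, 200
        t = np.arange(T) * tr
        tc = _scan(np.column_stack([np.cos(2 * np.pi * f * t)] * 2), tr)
        tsn = _scan(np.column_stack([np.sin(2 * np.pi * f * t)] * 2), tr)
        lag = instantaneous_phase(tc)[:, 0] - instantaneous_phase(tsn)[:, 0]
        lag = np.angle(np.exp(1j * lag))
        np.testing.assert_allclose(lag[20:-20], np.pi / 2, atol=0.05)

    def test_all_zero_column_rejected(self):
        data = np.column_stack([np.zeros(50), np.random.default_rng(0).normal(size=50)])
        with pytest.raises(DegenerateSignalError):
            instantaneous_phase(_scan(data))


class TestPhaseCoherence:
    def test_small_example(self):
        C = phase_coherence(np.array([0.0, 0.0, np.pi]))
        np.testing.assert_allclose(
            C, [[1, 1, -1], [1, 1, -1], [-1, -1, 1]], atol=1e-12
        )

    def test_equal_phases_give_all_ones(self):
        C = phase_coherence(np.full(5, 1.3))
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_two_identity(self, seed):
        """C = cc^T + ss^T: eigenvalues >= 0, rank <= 2, l1 + l2 = N."""
        theta = np.random.default_rng(seed).uniform(-np.pi, np.pi, size=10)
        C = phase_coherence(theta)
        eigvals = np.linalg.eigvalsh(C)  # independent full decomposition
        assert eigvals.min() >= -1e-10
        assert eigvals[-1] + eigvals[-2] == pytest.approx(10.0, abs=1e-8)
        assert (np.abs(eigvals[:-2]) < 1e-8).all()
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)

    @given(
        theta=hnp.arrays(float, 8, elements=st.floats(-3.1, 3.1)),
        shift=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_global_phase_shift_invariance(self, theta, shift):
        np.testing.assert_allclose(
            phase_coherence(theta + shift), phase_coherence(theta), atol=1e-9
        )


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v = leading_eigenvector(np.ones((4, 4)))
        np.testing.assert_allclose(v, 0.5, atol=1e-12)

    def test_rank_one_coherence(self):
        C = phase_coherence(np.array([0.0, 0.0, np.pi]))
        v = leading_eigenvector(C)
        np.testing.assert_allclose(v, np.array([1, 1, -1]) / np.sqrt(3), atol=1e-10)

    def test_agrees_with_dense_solver_on_random_coherence(self):
        """Rank-2 fast path vs a full dense eigendecomposition oracle."""
        from leida.phase import _canonicalize_rows, _leading_from_phases

        rng = np.random.default_rng(42)
        theta = rng.uniform(-np.pi, np.pi, size=(100, 10))
        fast = _canonicalize_rows(_leading_from_phases(theta))
        for i in range(100):
            C = phase_coherence(theta[i])
            eigvals, eigvecs = np.linalg.eigh(C)
            oracle = eigvecs[:, -1]
            assert abs(fast[i] @ oracle) > 1 - 1e-8
            assert abs(leading_eigenvector(C) @ oracle) > 1 - 1e-8

    def test_degenerate_top_eigenspace_warns(self):
        with pytest.warns(RuntimeWarning):
            leading_eigenvector(np.eye(4))

    @given(hnp.arrays(float, 7, elements=st.floats(-5, 5)).filter(
        lambda v: np.linalg.norm(v) > 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_canonicalization_idempotent_and_even(self, v):
        c = canonicalize_sign(v)
        np.testing.assert_array_equal(canonicalize_sign(c), c)
        np.testing.assert_array_equal(canonicalize_sign(-v), c)


class TestEigenvectorSeries:
    def test_edge_volumes_trimmed(self):
        rng = np.random.default_rng(0)
        ts = _scan(rng.normal(size=(200, 8)))
        les = eigenvector_series(ts, band=None)
        assert les.n_vectors == 198
        np.testing.assert_array_equal(les.volume_index, np.arange(1, 199))

    def test_rows_unit_norm_and_canonical(self, small_stack):
        norms = np.linalg.norm(small_stack.matrix, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        sums = small_stack.matrix.sum(axis=1)
        pivots = np.argmax(np.abs(small_stack.matrix), axis=1)
        ok = (sums > 0) | (
            (np.abs(sums) < 1e-12)
            & (small_stack.matrix[np.arange(len(sums)), pivots] > 0)
        )
        assert ok.all()

    def test_single_planted_state_recovered(self, single_state_scan):
        """A scan locked in one state yields eigenvectors along its template."""
        ts, labels, templates = single_state_scan
        assert (labels == 1).all()
        les = eigenvector_series(ts, band=None)
        sims = np.abs(les.vectors @ templates[0].values)
        assert sims.min() > 0.97
        assert np.median(sims) > 0.99
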