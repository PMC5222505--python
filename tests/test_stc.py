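"""Tests for STA/STC transforms, eigenanalysis, and shift-null significance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wienerstc as w
from wienerstc.exceptions import (
    DegenerateInputError,
    DimensionError,
    ValidationError,
)
from wienerstc.stc import stc_raw, stc_sta_projected, stc_sta_subtracted

from conftest import random_spike_instance
from oracles import definitional_c1, definitional_c2, window_vector


class TestSpikeTriggeredAverage:
    def test_worked_example(self, worked):
        sta = w.spike_triggered_average(
            worked["stimulus"], worked["spikes"], worked["lags"]
        )
        np.testing.assert_allclose(sta.a, worked["a"], rtol=1e-14)
        assert sta.n_r == worked["n_r"]

    def test_single_spike_returns_its_window(self):
        stim = w.gaussian_white_stimulus(40, 2, seed=0)
        tau = 4
        spikes = np.zeros(40)
        t0 = 17
        spikes[t0] = 1.0
        sta = w.spike_triggered_average(stim, spikes, w.LagWindow(tau))
        np.testing.assert_array_equal(sta.a, window_vector(stim.values, t0, tau))
        assert sta.n_r == 1.0

    def test_no_spikes_is_degenerate(self):
        stim = w.gaussian_white_stimulus(20, 1, seed=0)
        with pytest.raises(DegenerateInputError):
            w.spike_triggered_average(stim, np.zeros(20), w.LagWindow(2))

    def test_spikes_only_counted_inside_full_windows(self):
        # a spike in the warm-up bins has no complete window and is excluded
        stim = w.gaussian_white_stimulus(20, 1, seed=1)
        spikes = np.zeros(20)
        spikes[0] = 5.0
        with pytest.raises(DegenerateInputError):
            w.spike_triggered_average(stim, spikes, w.LagWindow(3))

    def test_rejects_continuous_or_negative_responses(self):
        stim = w.gaussian_white_stimulus(20, 1, seed=0)
        cont = w.ResponseSet(np.random.default_rng(0).normal(size=20))
        with pytest.raises(ValidationError):
            w.spike_triggered_average(stim, cont, w.LagWindow(2))
        with pytest.raises(ValidationError):
            w.spike_triggered_average(stim, -np.ones(20), w.LagWindow(2))


class TestSTCMatrices:
    def test_worked_example_c0(self, worked):
        res = w.compute_stc(worked["stimulus"], worked["spikes"], worked["lags"])
        np.testing.assert_allclose(res.C0, worked["C0"], rtol=1e-13)

    def test_worked_example_c1_and_outer_product(self, worked):
        res = w.compute_stc(worked["stimulus"], worked["spikes"], worked["lags"])
        np.testing.assert_allclose(res.A, worked["A"], rtol=1e-13)
        np.testing.assert_allclose(res.C1, worked["C1"], rtol=1e-13)

    def test_unit_response_gives_zero_c0_exactly(self):
        stim = w.gaussian_white_stimulus(300, 2, seed=2)
        ones = w.ResponseSet(np.ones(300), mode=w.MODE_SPIKES)
        res = w.compute_stc(stim, ones, w.LagWindow(4))
        assert np.all(res.C0 == 0.0)

    def test_c0_invariant_under_response_doubling(self, worked):
        res1 = w.compute_stc(worked["stimulus"], worked["spikes"], worked["lags"])
        doubled = w.ResponseSet(2.0 * worked["spikes"].values, mode=w.MODE_SPIKES)
        res2 = w.compute_stc(worked["stimulus"], doubled, worked["lags"])
        np.testing.assert_allclose(res1.C0, res2.C0, rtol=1e-13)

    def test_c0_requires_raw_counts(self, worked):
        C = w.response_weighted_covariance(
            worked["stimulus"], worked["spikes"], worked["lags"],
            demean_response=True,
        )[0]
        S = w.stimulus_covariance(worked["stimulus"], worked["lags"])
        with pytest.raises(ValidationError):
            stc_raw(C, S, 4, 1, 3.0)

    def test_zero_sta_leaves_c0_unchanged_in_c1(self):
        C0 = np.array([[2.0, 1.0], [1.0, 3.0]])
        sta = w.SpikeTriggeredAverage(a=np.zeros(2), n_r=1.0)
        np.testing.assert_array_equal(stc_sta_subtracted(C0, sta), C0)

    def test_zero_sta_makes_projector_degenerate(self):
        C0 = np.eye(2)
        sta = w.SpikeTriggeredAverage(a=np.zeros(2), n_r=1.0)
        with pytest.raises(DegenerateInputError):
            stc_sta_projected(C0, sta)

    def test_axis_aligned_sta_zeroes_first_row_and_column(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(4, 4))
        C0 = (M + M.T) / 2
        sta = w.SpikeTriggeredAverage(a=np.array([2.5, 0, 0, 0]), n_r=3.0)
        C2 = stc_sta_projected(C0, sta)
        np.testing.assert_allclose(C2[0, :], 0.0, atol=1e-14)
        np.testing.assert_allclose(C2[:, 0], 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_definitional_forms_match_transforms(self, seed):
        """C1 and C2 from their pre-simplification sums equal the
        matrix-transform forms on random spike trains."""
        stim, spikes, lags = random_spike_instance(seed, T=300, D=2, tau=3)
        res = w.compute_stc(stim, spikes, lags)
        c1_def = definitional_c1(stim.values, spikes, lags.tau)
        c2_def = definitional_c2(stim.values, spikes, lags.tau)
        scale1 = max(1.0, np.abs(res.C1).max())
        scale2 = max(1.0, np.abs(res.C2).max())
        np.testing.assert_allclose(res.C1, c1_def, rtol=0, atol=1e-10 * scale1)
        np.testing.assert_allclose(res.C2, c2_def, rtol=0, atol=1e-10 * scale2)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_c2_annihilates_the_sta(self, seed):
        stim, spikes, lags = random_spike_instance(seed, T=300, D=1, tau=5)
        res = w.compute_stc(stim, spikes, lags)
        bound = 1e-10 * np.linalg.norm(res.C2) * np.linalg.norm(res.sta.a)
        assert np.abs(res.C2 @ res.sta.a).max() <= max(bound, 1e-12)

    def test_projector_is_symmetric_and_idempotent(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=6)
        P = np.eye(6) - np.outer(a, a) / (a @ a)
        np.testing.assert_allclose(P, P.T, atol=1e-14)
        np.testing.assert_allclose(P @ P, P, atol=1e-13)


class TestEigendecompose:
    def test_identity_all_ones(self):
        rep = w.eigendecompose(np.eye(3))
        np.testing.assert_array_equal(rep.eigenvalues, np.ones(3))

    def test_diagonal_sorted_descending(self):
        rep = w.eigendecompose(np.diag([3.0, 1.0, 2.0]))
        np.testing.assert_array_equal(rep.eigenvalues, [3.0, 2.0, 1.0])

    def test_closed_form_two_by_two(self):
        rep = w.eigendecompose(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(rep.eigenvalues, [3.0, 1.0], rtol=1e-14)
        np.testing.assert_allclose(
            np.abs(rep.eigenvectors[:, 0]), np.full(2, 1 / np.sqrt(2)), rtol=1e-12
        )
        # sign convention: the largest-magnitude component is positive
        assert np.all(rep.eigenvectors[np.argmax(np.abs(rep.eigenvectors), 0),
                                       range(2)] > 0)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValidationError):
            w.eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 8))
    def test_orthonormality_and_reconstruction(self, seed, n):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(n, n))
        M = (M + M.T) / 2
        rep = w.eigendecompose(M)
        V, lam = rep.eigenvectors, rep.eigenvalues
        np.testing.assert_allclose(V.T @ V, np.eye(n), atol=1e-10)
        np.testing.assert_allclose(V @ np.diag(lam) @ V.T, M, atol=1e-10)
        assert np.all(np.diff(lam) <= 1e-12)


class TestShiftNull:
    def test_same_seed_same_ensemble(self):
        stim, spikes, lags = random_spike_instance(0, T=500, tau=3)
        kw = dict(n_shifts=20, seed=42, matrix_variant="C0")
        n1 = w.shift_null_ensemble(stim, spikes, lags, **kw)
        n2 = w.shift_null_ensemble(stim, spikes, lags, **kw)
        np.testing.assert_array_equal(n1.shifts, n2.shifts)
        np.testing.assert_array_equal(n1.spectra, n2.spectra)

    def test_different_seed_different_shifts(self):
        stim, spikes, lags = random_spike_instance(0, T=500, tau=3)
        n1 = w.shift_null_ensemble(stim, spikes, lags, n_shifts=20, seed=1)
        n2 = w.shift_null_ensemble(stim, spikes, lags, n_shifts=20, seed=2)
        assert not np.array_equal(n1.shifts, n2.shifts)

    def test_zero_response_gives_zero_kernels(self):
        stim = w.gaussian_white_stimulus(400, 1, seed=0)
        null = w.shift_null_ensemble(
            stim, np.zeros(400), w.LagWindow(3), n_shifts=5, seed=0,
            matrix_variant="C", store_matrices=True,
        )
        assert all(np.all(K == 0.0) for K in null.kernels)
        assert np.all(null.spectra == 0.0)

    def test_zero_spikes_degenerate_for_stc_variants(self):
        stim = w.gaussian_white_stimulus(400, 1, seed=0)
        with pytest.raises(DegenerateInputError):
            w.shift_null_ensemble(
                stim, np.zeros(400), w.LagWindow(3), n_shifts=5, seed=0,
                matrix_variant="C0",
            )

    def test_min_shift_must_exceed_tau(self):
        stim, spikes, lags = random_spike_instance(0, T=500, tau=3)
        with pytest.raises(ValidationError):
            w.shift_null_ensemble(
                stim, spikes, lags, n_shifts=5, min_shift=3, seed=0
            )

    def test_needs_at_least_two_shifts(self):
        stim, spikes, lags = random_spike_instance(0, T=500, tau=3)
        with pytest.raises(ValidationError):
            w.shift_null_ensemble(stim, spikes, lags, n_shifts=1, seed=0)

    def test_all_shifts_distinct_and_beyond_tau(self):
        stim, spikes, lags = random_spike_instance(1, T=500, tau=4)
        null = w.shift_null_ensemble(stim, spikes, lags, n_shifts=50, seed=3)
        assert np.unique(null.shifts).size == 50
        assert np.all(np.abs(null.shifts) > lags.tau)


class TestSignificance:
    def _synthetic_null(self, n_shifts=99, n_eig=4, seed=0):
        rng = np.random.default_rng(seed)
        spectra = -np.sort(-rng.normal(size=(n_shifts, n_eig)), axis=1)
        shifts = np.arange(10, 10 + n_shifts)
        return w.NullEnsemble(
            shifts=shifts, spectra=spectra, seed=seed, variant="C0", tau=2
        )

    def test_null_median_spectrum_is_never_significant(self):
        null = self._synthetic_null()
        median = np.median(null.spectra, axis=0)
        for method in ("rank", "extreme"):
            mask = w.significant_eigenvalues(median, null, 0.05, method=method)
            assert not mask.any()

    def test_alpha_one_flags_everything_under_rank_bands(self):
        null = self._synthetic_null()
        obs = np.median(null.spectra, axis=0) + 1e-6  # distinct from the medians
        mask = w.significant_eigenvalues(obs, null, alpha=1.0, method="rank")
        assert mask.all()

    def test_large_eigenvalue_is_flagged(self):
        null = self._synthetic_null()
        obs = np.median(null.spectra, axis=0)
        obs[0] = 100.0
        for method in ("rank", "extreme"):
            mask = w.significant_eigenvalues(obs, null, 0.05, method=method)
            assert mask[0] and not mask[1:].any()

    def test_spectrum_length_must_match(self):
        null = self._synthetic_null(n_eig=4)
        with pytest.raises(DimensionError):
            w.significant_eigenvalues(np.zeros(3), null, 0.05)

    def test_unknown_method_rejected(self):
        null = self._synthetic_null()
        with pytest.raises(ValidationError):
            w.significant_eigenvalues(np.zeros(4), null, 0.05, method="bogus")


class TestFilterSubspace:
    def test_verbatim_filter_has_unit_similarity(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=8)
        basis = np.column_stack([f, rng.normal(size=8)])
        sims = w.filter_subspace_check(basis, f)
        np.testing.assert_allclose(sims, [1.0], atol=1e-12)

    def test_orthogonal_filter_has_zero_similarity(self):
        basis = np.eye(4)[:, :2]
        f = np.array([0.0, 0.0, 1.0, 0.0])
        sims = w.filter_subspace_check(basis, f)
        np.testing.assert_allclose(sims, [0.0], atol=1e-12)

    def test_empty_vector_set_rejected(self):
        with pytest.raises(ValidationError):
            w.filter_subspace_check([], np.ones(4))


def test_sta_mixes_the_two_filters():
    """In the two-filter cell the STA resembles neither filter alone but
    lies almost inside their span."""
    T, L = 2**16, 8
    stim = w.gaussian_white_stimulus(T, 1, seed=11)
    cell = w.two_filter_lnp(L, target_rate=0.02)  # higher rate: tighter STA
    resp = w.lnp_spikes(stim, cell, seed=12)
    sta = w.spike_triggered_average(stim, resp, w.LagWindow(L - 1))
    a = sta.a / np.linalg.norm(sta.a)
    f1, f2 = cell.filters
    single = max(abs(a @ f1), abs(a @ f2))
    combined = w.filter_subspace_check(np.column_stack([f1, f2]), a)[0]
    assert single < 0.85
    assert combined > 0.97
    assert combined - single > 0.1
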