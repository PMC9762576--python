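"""Binning, NMF fitting, module-count selection and projections."""

import numpy as np
import pandas as pd
import pytest

from popcode.afferents import AfferentPopulation, SpikeDataset
from popcode.decomposition import (
    ResponseMatrix,
    bin_raster,
    explained_variance,
    fit_nmf,
    make_split,
    project,
    select_num_modules,
    spatial_nmf,
)


def _dataset(times, trial_idx, aff_idx, n_trials=1, n_aff=1, duration=0.5):
    pop = AfferentPopulation("SA1", 1.0, 1.0, np.linspace(0, 1, n_aff))
    labels = pd.DataFrame({"trial": np.arange(n_trials), "condition_id": np.zeros(n_trials, int)})
    return SpikeDataset(
        class_label="SA1", density_per_cm2=1.0, population=pop, n_trials=n_trials,
        duration_s=duration, trial_idx=np.asarray(trial_idx, dtype=np.int64),
        aff_idx=np.asarray(aff_idx, dtype=np.int64), times=np.asarray(times, float),
        labels=labels,
    )


class TestBinning:
    def test_example_spike_counts(self):
        ds = _dataset([0.0001, 0.0015, 0.0021], [0, 0, 0], [0, 0, 0], duration=0.01)
        R = bin_raster(ds, 0.002)
        assert R.R[0, 0] == 2 and R.R[0, 1] == 1
        assert R.R.sum() == 3

    def test_empty_dataset_gives_zero_matrix(self):
        ds = _dataset([], [], [], n_trials=2, n_aff=3)
        R = bin_raster(ds, 0.002)
        assert R.R.shape == (2, 3 * 250)
        assert not R.R.any()

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 0.5, 200)
        ds = _dataset(times, rng.integers(0, 4, 200), rng.integers(0, 3, 200),
                      n_trials=4, n_aff=3)
        assert bin_raster(ds).R.sum() == 200

    def test_afferent_major_time_minor_layout(self):
        # one spike of afferent 1 in bin 0 must land at column 1*T + 0
        ds = _dataset([0.0005], [0], [1], n_trials=1, n_aff=2, duration=0.01)
        R = bin_raster(ds, 0.002)
        T = R.n_time_bins
        assert R.R[0, T] == 1

    def test_out_of_window_spike_rejected(self):
        ds = _dataset([0.7], [0], [0])
        with pytest.raises(ValueError):
            bin_raster(ds)

    def test_bin_width_must_divide_duration(self):
        ds = _dataset([0.1], [0], [0])
        with pytest.raises(ValueError):
            bin_raster(ds, 0.0003)


class TestFitNMF:
    def test_exact_rank_one_recovery(self):
        h = np.random.default_rng(1).uniform(0, 1, 20)
        w = np.random.default_rng(2).uniform(0, 1, 50)
        X = np.outer(h, w)
        m = fit_nmf(X, 1, seed=0)
        assert m.explained_variance >= 0.999

    def test_zero_matrix_convention(self):
        m = fit_nmf(np.zeros((5, 8)), 2, seed=0)
        assert m.explained_variance == 1.0
        assert not m.H.any() and not m.W.any()

    def test_invalid_k_rejected(self):
        X = np.ones((4, 6))
        for K in (0, 5):
            with pytest.raises(ValueError):
                fit_nmf(X, K)

    def test_factors_non_negative(self):
        X = np.random.default_rng(3).uniform(0, 1, (10, 30))
        m = fit_nmf(X, 3, seed=1)
        assert (m.W >= 0).all() and (m.H >= 0).all()


class TestModuleSelection:
    @staticmethod
    def _rank_r_data(r, noise_sd=0.01, m=60, n=120, seed=0):
        rng = np.random.default_rng(seed)
        H = rng.uniform(0.5, 1.5, (m, r)) * (rng.random((m, r)) < 0.5)
        H[np.arange(m), rng.integers(0, r, m)] = rng.uniform(0.5, 1.5, m)  # every trial active
        W = rng.uniform(0, 1, (r, n)) * (rng.random((r, n)) < 0.3)
        X = H @ W + rng.normal(0, noise_sd, (m, n))
        return np.clip(X, 0, None)

    def test_recovers_known_rank(self):
        X = self._rank_r_data(3)
        sel = select_num_modules({0.0: X}, seed=0, k_max=8)
        assert sel.k_per_density[0.0] == 3
        assert sel.class_threshold > 0.9

    def test_noiseless_rank_one_selects_one_module(self):
        X = self._rank_r_data(1, noise_sd=0.0)
        sel = select_num_modules({0.0: X}, seed=0, k_max=5)
        assert sel.k_per_density[0.0] == 1

    def test_immediate_saturation_selects_one_module(self):
        # uniform matrix: K=1 explains everything, all gains < tolerance
        X = np.ones((10, 20))
        sel = select_num_modules({0.0: X}, seed=0, k_max=5)
        assert sel.k_per_density[0.0] == 1


class TestProject:
    def test_projection_consistent_with_fit(self):
        X = TestModuleSelection._rank_r_data(2, noise_sd=0.005)
        m = fit_nmf(X, 2, seed=0)
        H = project(X, m.W)
        ev_fit = m.explained_variance
        ev_proj = explained_variance(X, H, m.W)
        assert ev_proj >= ev_fit - 0.01

    def test_single_module_equal_to_row_reconstructs_exactly(self):
        X = np.random.default_rng(4).uniform(0, 1, (5, 12))
        W = X[2:3].copy()
        H = project(X, W)
        assert H[2, 0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(H[2] @ W, X[2])

    def test_coefficients_non_negative(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (8, 20))
        W = rng.uniform(0, 1, (3, 20))
        assert (project(X, W) >= 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project(np.ones((3, 10)), np.ones((2, 8)))


class TestSpatialNMF:
    def test_two_disjoint_groups_yield_two_supported_modules(self):
        # afferents 0-2 co-active in half the trials, 3-5 in the other half
        rng = np.random.default_rng(6)
        M, N, T = 40, 6, 10
        R3 = np.zeros((M, N, T))
        for m in range(M):
            grp = slice(0, 3) if m % 2 == 0 else slice(3, 6)
            R3[m, grp] = rng.poisson(3.0, (3, T))
        R = ResponseMatrix(R3.reshape(M, N * T), T, N, 0.002)
        res = spatial_nmf(R, K=2, seed=0)
        assert res.K_space == 2
        for k in range(2):
            w = res.W_space[k]
            support = w > 0.1 * w.max()
            assert support[:3].all() != support[3:].all()  # one group each

    def test_coefficient_count_is_modules_times_bins(self):
        rng = np.random.default_rng(7)
        M, N, T = 12, 4, 25
        R = ResponseMatrix(rng.poisson(1.0, (M, N * T)).astype(float), T, N, 0.002)
        res = spatial_nmf(R, K=3, seed=0)
        assert res.H_t.shape == (M, 3 * T)

    def test_single_afferent_coefficients_track_counts(self):
        M, N, T = 6, 1, 20
        rng = np.random.default_rng(8)
        R3 = rng.poisson(2.0, (M, N, T)).astype(float)
        R = ResponseMatrix(R3.reshape(M, N * T), T, N, 0.002)
        res = spatial_nmf(R, K=1, seed=0)
        scale = res.W_space[0, 0]
        assert np.allclose(res.H_t.reshape(M, T) * scale, R3[:, 0, :], atol=1e-8)


class TestSplit:
    def test_stratified_fractions(self):
        cond = np.repeat(np.arange(10), 20)
        sel, ana = make_split(cond, 0.25, seed=0)
        assert sel.sum() == 50 and ana.sum() == 150
        for c in range(10):
            assert sel[cond == c].sum() == 5

    def test_every_condition_in_both_sets(self):
        cond = np.repeat(np.arange(5), 2)
        sel, ana = make_split(cond, 0.25, seed=1)
        for c in range(5):
            assert sel[cond == c].any() and ana[cond == c].any()

    def test_single_trial_condition_rejected(self):
        with pytest.raises(ValueError):
            make_split(np.array([0, 0, 1]), 0.25, seed=0)
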