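"""CSP / FBCSP correctness: covariances, the GEVD, features, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_spd, sinusoid_trial
from ssvepid.data import Trial, TrialSet
from ssvepid.errors import (
    DegenerateTrialError,
    InvalidConfigError,
    InvalidInputError,
    InvalidTrainingSetError,
)
from ssvepid.fbcsp import (
    ClassCovariances,
    CSPModel,
    class_covariance,
    csp_objective,
    csp_pair,
    extract_features,
    fit_fbcsp_ovr,
    log_variances,
    spatial_covariance,
)
from ssvepid.preprocessing import BandSpec, FilterBank
from ssvepid.synthetic import SimConfig, simulate_dataset


def make_trial(data, subject_id=1, block=1):
    return Trial(
        data=np.asarray(data, dtype=float),
        fs_hz=250.0,
        subject_id=subject_id,
        block_index=block,
        stim_freq_hz=10.0,
    )


class TestSpatialCovariance:
    def test_hand_example_identical_rows(self):
        trial = make_trial([[1, -1, 1, -1], [1, -1, 1, -1]])
        c = spatial_covariance(trial)
        # X X' = [[4,4],[4,4]], trace 8 -> every entry 0.5; trace(c) = 1
        np.testing.assert_allclose(c, [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)
        assert np.trace(c) == pytest.approx(1.0, abs=1e-15)
        assert np.linalg.matrix_rank(c) == 1

    def test_unit_trace(self, small_trialset):
        for trial in small_trialset.trials[:5]:
            assert np.trace(spatial_covariance(trial)) == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_channels_have_small_off_diagonal(self):
        rng = np.random.default_rng(0)
        nt = 20000
        trial = make_trial(rng.standard_normal((2, nt)))
        c = spatial_covariance(trial)
        # unit-trace normalization puts each diagonal near 1/2
        assert abs(c[0, 1] / c[0, 0]) < 3.0 / np.sqrt(nt)

    def test_zero_trial_rejected(self):
        with pytest.raises(DegenerateTrialError):
            spatial_covariance(make_trial(np.zeros((2, 8))))


class TestClassCovariance:
    def test_single_trial_equals_loaded_covariance(self):
        trial = make_trial(np.random.default_rng(1).standard_normal((3, 50)))
        c1 = class_covariance([trial], shrinkage=0.0)
        np.testing.assert_allclose(c1, spatial_covariance(trial), atol=1e-15)

    def test_mean_is_idempotent_for_duplicates(self):
        trial = make_trial(np.random.default_rng(2).standard_normal((3, 50)))
        a = class_covariance([trial, trial, trial])
        b = class_covariance([trial])
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_full_shrinkage_gives_scaled_identity(self):
        trial = make_trial(np.random.default_rng(3).standard_normal((4, 50)))
        c = class_covariance([trial], shrinkage=1.0)
        np.testing.assert_allclose(c, np.eye(4) / 4.0, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            class_covariance([])


class TestCSPPair:
    def test_hand_solved_2x2_problem(self):
        cov = ClassCovariances(c1=np.diag([2.0, 1.0]) / 3, c2=np.diag([1.0, 2.0]) / 3)
        w, lam = csp_pair(cov, p=1)
        np.testing.assert_allclose(lam, [2.0, 0.5], atol=1e-12)
        # columns align with the axes (up to the c2-normalization scaling)
        assert abs(w[1, 0]) < 1e-12 and abs(w[0, 1]) < 1e-12
        # w' c2 w = 1 per column
        for j in range(2):
            assert w[:, j] @ cov.c2 @ w[:, j] == pytest.approx(1.0, abs=1e-12)

    def test_identical_classes_give_unit_eigenvalues(self):
        c = random_spd(np.random.default_rng(5), 4)
        _, lam = csp_pair(ClassCovariances(c1=c, c2=c), p=2)
        np.testing.assert_allclose(lam, 1.0, atol=1e-10)

    def test_top_filter_is_extremal(self):
        rng = np.random.default_rng(7)
        c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
        w, lam = csp_pair(ClassCovariances(c1=c1, c2=c2), p=1)
        j_top = csp_objective(w[:, 0], c1, c2)
        v = rng.standard_normal((10000, 4))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        j_rand = np.einsum("ij,jk,ik->i", v, c1, v) / np.einsum("ij,jk,ik->i", v, c2, v)
        assert j_top >= j_rand.max() - 1e-9

    def test_too_many_filters_rejected(self):
        c = random_spd(np.random.default_rng(1), 3)
        with pytest.raises(InvalidConfigError):
            csp_pair(ClassCovariances(c1=c, c2=c), p=2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=4, max_value=9), st.integers(min_value=0, max_value=10**6))
    def test_gevd_residual_and_whitening(self, n, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = random_spd(rng, n), random_spd(rng, n)
        p = min(2, n // 2)
        w, lam = csp_pair(ClassCovariances(c1=c1, c2=c2), p=p)
        kept = np.concatenate([lam[:p], lam[n - p :]])
        for j in range(2 * p):
            resid = np.max(np.abs(c1 @ w[:, j] - kept[j] * (c2 @ w[:, j])))
            assert resid < 1e-8
        np.testing.assert_allclose(np.diag(w.T @ c2 @ w), 1.0, atol=1e-8)


class TestLogVariances:
    def test_unit_variance_maps_to_zero(self):
        logv, clamped = log_variances(np.array([1.0, -1.0, 1.0, -1.0])[:, None])
        assert logv[0] == 0.0 and not clamped

    def test_variance_four_maps_to_ln4(self):
        logv, _ = log_variances(np.array([2.0, -2.0, 2.0, -2.0])[:, None])
        assert logv[0] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_zero_variance_clamped_and_flagged(self):
        logv, clamped = log_variances(np.ones((8, 1)))
        assert clamped and logv[0] == pytest.approx(np.log(1e-12))


class TestFitOVR:
    def test_feature_dim_formula(self, small_trialset):
        # Np classes x B bands x 2p filters
        bank = FilterBank(bands=(BandSpec(8.0, 19.0), BandSpec(19.0, 30.0)))
        model = fit_fbcsp_ovr(small_trialset, bank, p=2)
        assert model.feature_dim == 4 * 2 * 2 * 2

    def test_three_class_dim_example(self):
        config = SimConfig(
            n_subjects=3, n_blocks=2, trial_duration_s=1.0, n_channels=6, seed=5
        )
        ts = simulate_dataset(config)
        bank = FilterBank(bands=(BandSpec(8.0, 19.0), BandSpec(19.0, 30.0)))
        model = fit_fbcsp_ovr(ts, bank, p=2)
        assert model.feature_dim == 3 * 2 * 2 * 2 == 24

    def test_two_class_problems_are_mirror_images(self):
        config = SimConfig(
            n_subjects=2, n_blocks=3, trial_duration_s=2.0, n_channels=5, seed=8
        )
        ts = simulate_dataset(config)
        bank = FilterBank(bands=(BandSpec(8.0, 30.0),))
        model = fit_fbcsp_ovr(ts, bank, p=1)
        w1, w2 = model.filters[(0, 0)], model.filters[(1, 0)]
        # class-1 top filter spans the same direction as class-2 bottom filter
        for a, b in ((w1[:, 0], w2[:, 1]), (w1[:, 1], w2[:, 0])):
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-8)
        lam1, lam2 = model.eigenvalues[(0, 0)], model.eigenvalues[(1, 0)]
        np.testing.assert_allclose(np.sort(lam1), np.sort(1.0 / lam2), rtol=1e-6)

    def test_deterministic(self, small_trialset, two_band_bank):
        a = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        b = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        for key in a.filters:
            np.testing.assert_array_equal(a.filters[key], b.filters[key])

    def test_mixed_frequencies_rejected(self, small_trialset):
        bad = TrialSet(list(small_trialset.trials), 4, 3, [10.0, 12.0])
        bad.trials[0].stim_freq_hz = 12.0
        with pytest.raises(InvalidTrainingSetError):
            fit_fbcsp_ovr(bad, FilterBank(bands=(BandSpec(8.0, 30.0),)), p=1)
        bad.trials[0].stim_freq_hz = 10.0


class TestExtractFeatures:
    def test_length_and_finiteness(self, small_trialset, two_band_bank):
        model = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        for trial in small_trialset.trials:
            f = extract_features(trial, model)
            assert f.values.shape == (model.feature_dim,)
            assert np.all(np.isfinite(f.values))
            assert f.subject_label == trial.subject_id

    def test_scaling_shifts_features_by_ln100(self, small_trialset, two_band_bank):
        model = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        trial = small_trialset.trials[0]
        f = extract_features(trial, model)
        f10 = extract_features(trial.with_data(10.0 * trial.data), model)
        np.testing.assert_allclose(f10.values - f.values, np.log(100.0), atol=1e-9)

    def test_discrimination_between_and_within_class(self, small_trialset, two_band_bank):
        # subject-specific mixing at 10 dB: between-class feature distance
        # must exceed within-class distance
        model = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        feats = [extract_features(t, model) for t in small_trialset.trials]
        within, between = [], []
        for i, a in enumerate(feats):
            for b in feats[i + 1 :]:
                d = np.linalg.norm(a.values - b.values)
                (within if a.subject_label == b.subject_label else between).append(d)
        assert np.mean(between) > np.mean(within)

    def test_channel_count_mismatch_rejected(self, small_trialset, two_band_bank):
        model = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
        bad = sinusoid_trial(10.0, n_channels=3)
        with pytest.raises(InvalidInputError):
            extract_features(bad, model)


def test_model_serialization_round_trip(tmp_path, small_trialset, two_band_bank):
    model = fit_fbcsp_ovr(small_trialset, two_band_bank, p=2)
    path = tmp_path / "csp.npz"
    model.save(path)
    loaded = CSPModel.load(path)
    assert loaded.p == model.p
    assert loaded.classes == model.classes
    assert loaded.bands.edges() == model.bands.edges()
    for key in model.filters:
        np.testing.assert_array_equal(loaded.filters[key], model.filters[key])
        np.testing.assert_array_equal(loaded.eigenvalues[key], model.eigenvalues[key])
    trial = small_trialset.trials[0]
    np.testing.assert_array_equal(
        extract_features(trial, loaded).values, extract_features(trial, model).values
    )
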