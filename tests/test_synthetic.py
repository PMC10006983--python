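"""Generator contracts: determinism, spectra, SNR calibration, separability."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.linalg import subspace_angles

from ssvepid.errors import InvalidConfigError, InvalidInputError
from ssvepid.synthetic import (
    SimConfig,
    SubjectModel,
    _source_signals,
    _subject_models,
    make_subject,
    simulate_dataset,
    simulate_trial,
)


class TestMakeSubject:
    def test_fixed_seed_is_deterministic(self):
        a = make_subject(seed=1, n_channels=9, n_sources=2, snr_db=5.0)
        b = make_subject(seed=1, n_channels=9, n_sources=2, snr_db=5.0)
        np.testing.assert_array_equal(a.mixing_matrix, b.mixing_matrix)
        np.testing.assert_array_equal(a.harmonic_phases, b.harmonic_phases)
        assert a.snr_db == b.snr_db

    def test_distinct_seeds_differ(self):
        a = make_subject(seed=1, n_channels=9, n_sources=2, snr_db=5.0)
        b = make_subject(seed=2, n_channels=9, n_sources=2, snr_db=5.0)
        assert np.any(a.mixing_matrix != b.mixing_matrix)

    def test_mixing_columns_are_unit_norm(self):
        s = make_subject(seed=7, n_channels=4, n_sources=2, snr_db=0.0)
        norms = np.linalg.norm(s.mixing_matrix, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_too_many_sources_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_subject(seed=0, n_channels=2, n_sources=3, snr_db=0.0)


class TestSimulateTrial:
    def _config(self, **kw):
        defaults = dict(
            n_subjects=2,
            n_blocks=2,
            stim_frequencies_hz=(10.0,),
            fs_hz=250.0,
            trial_duration_s=4.0,
            n_channels=4,
            seed=0,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_noiseless_spectrum_peaks_at_stimulus_frequency(self):
        # FFT oracle: with the noise floor removed, each channel that sees the
        # source must peak at the bin nearest f_stim
        config = self._config(snr_db=200.0, noise_model="white")
        subject = make_subject(seed=3, n_channels=4, n_sources=1, snr_db=200.0)
        trial = simulate_trial(subject, 10.0, config, np.random.default_rng(0))
        freqs, psd = sps.periodogram(trial.data, fs=config.fs_hz, axis=1)
        stim_bin = np.argmin(np.abs(freqs - 10.0))
        for ch in range(trial.n_channels):
            if abs(subject.mixing_matrix[ch, 0]) > 1e-6:
                assert np.argmax(psd[ch]) == stim_bin

    def test_zero_amplitude_subject_gives_white_noise(self):
        # autocorrelation oracle: pure-noise channels have |r| < 3/sqrt(Nt)
        # at the lag of one stimulus period
        config = self._config(snr_db=0.0, noise_model="white")
        subject = SubjectModel(
            subject_id=1,
            mixing_matrix=make_subject(1, 4, 1, 0.0).mixing_matrix,
            harmonic_amplitudes=np.zeros(3),
            harmonic_phases=np.zeros(3),
            snr_db=0.0,
        )
        trial = simulate_trial(subject, 10.0, config, np.random.default_rng(5))
        lag = int(round(config.fs_hz / 10.0))
        nt = trial.n_samples
        for row in trial.data:
            r = np.corrcoef(row[:-lag], row[lag:])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(nt)

    def test_same_rng_state_reproduces_samples(self):
        config = self._config(snr_db=5.0)
        subject = make_subject(seed=3, n_channels=4, n_sources=2, snr_db=5.0)
        t1 = simulate_trial(subject, 10.0, config, np.random.default_rng(42))
        t2 = simulate_trial(subject, 10.0, config, np.random.default_rng(42))
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_unknown_frequency_rejected(self):
        config = self._config()
        subject = make_subject(seed=3, n_channels=4, n_sources=2, snr_db=5.0)
        with pytest.raises(InvalidInputError):
            simulate_trial(subject, 17.3, config, np.random.default_rng(0))

    @pytest.mark.parametrize("noise_model", ["white", "white_plus_pink"])
    def test_realized_snr_within_1db(self, noise_model):
        config = self._config(snr_db=5.0, noise_model=noise_model, trial_duration_s=8.0)
        subject = make_subject(seed=9, n_channels=4, n_sources=2, snr_db=5.0)
        trial = simulate_trial(subject, 10.0, config, np.random.default_rng(1))
        clean = subject.mixing_matrix @ _source_signals(
            subject, 10.0, config.fs_hz, trial.n_samples
        )
        clean -= clean.mean(axis=1, keepdims=True)
        noise = trial.data - clean
        realized = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(realized - 5.0) < 1.0


class TestSimulateDataset:
    def test_counts(self):
        config = SimConfig(n_subjects=10, n_blocks=6, stim_frequencies_hz=(10.0,), seed=0)
        ts = simulate_dataset(config)
        assert len(ts) == 60
        for s in range(1, 11):
            assert sum(t.subject_id == s for t in ts.trials) == 6

    def test_pure_function_of_config(self):
        config = SimConfig(n_subjects=3, n_blocks=2, trial_duration_s=1.0, seed=4)
        a, b = simulate_dataset(config), simulate_dataset(config)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_adding_blocks_preserves_existing_trials(self):
        base = SimConfig(n_subjects=3, n_blocks=2, trial_duration_s=1.0, seed=4)
        more = SimConfig(n_subjects=3, n_blocks=4, trial_duration_s=1.0, seed=4)
        a, b = simulate_dataset(base), simulate_dataset(more)
        a_map = {(t.subject_id, t.block_index): t for t in a.trials}
        for t in b.trials:
            key = (t.subject_id, t.block_index)
            if key in a_map:
                np.testing.assert_array_equal(t.data, a_map[key].data)

    def test_separation_one_shares_one_mixing_matrix(self):
        config = SimConfig(n_subjects=4, n_blocks=2, subject_separation=1.0, seed=2)
        models = _subject_models(config)
        for m in models[1:]:
            np.testing.assert_allclose(m.mixing_matrix, models[0].mixing_matrix, atol=1e-12)

    def test_separability_monotone_in_separation(self):
        # mean pairwise principal angle between mixing column spaces shrinks
        # as the separation knob moves toward 1
        def mean_angle(sep):
            config = SimConfig(n_subjects=5, n_blocks=2, subject_separation=sep, seed=3)
            models = _subject_models(config)
            angles = [
                np.mean(subspace_angles(a.mixing_matrix, b.mixing_matrix))
                for i, a in enumerate(models)
                for b in models[i + 1 :]
            ]
            return float(np.mean(angles))

        angles = [mean_angle(s) for s in (0.0, 0.5, 0.9, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(angles, angles[1:]))
        assert angles[-1] < 1e-8

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_blocks=1)
        with pytest.raises(InvalidConfigError):
            SimConfig(stim_frequencies_hz=(-1.0,))
        with pytest.raises(InvalidConfigError):
            SimConfig(stim_frequencies_hz=(60.0,), fs_hz=250.0)  # harmonics alias
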