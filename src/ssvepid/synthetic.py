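"""Synthetic SSVEP trial generator.

The steady-state visual evoked potential is modelled as a small set of
stationary cortical sources oscillating at the stimulation frequency and its
harmonics.  Each subject owns a *spatial mixing pattern* — an
``n_channels x n_sources`` matrix describing how those sources project onto
the electrodes — and it is this pattern that encodes identity: two subjects
flickered at the same frequency produce the same narrowband content but mix
it differently across channels.  Broadband noise (white, or an equal-power
white + 1/f split mimicking the EEG background) is added at a configurable
channel-level SNR.

A single ``subject_separation`` knob interpolates all subjects' mixing
matrices toward a common base matrix (spherical interpolation per column):
at 0 every subject has an independent random pattern (easy identification),
at 1 all subjects share one pattern and identification collapses to chance.

Random streams are split per (subject, block, frequency) with
``numpy.random.SeedSequence``, so enlarging the design never perturbs
already-generated trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Trial, TrialSet
from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "SubjectModel",
    "SimConfig",
    "make_subject",
    "simulate_trial",
    "simulate_dataset",
    "DEFAULT_HARMONIC_AMPLITUDES",
]

#: Harmonic amplitude roll-off: fundamental plus two harmonics at -6 dB steps,
#: the typical occipital SSVEP profile.
DEFAULT_HARMONIC_AMPLITUDES = (1.0, 0.5, 0.25)


@dataclass
class SubjectModel:
    """Generative model of one subject's SSVEP response.

    ``mixing_matrix`` columns are unit-norm channel patterns, one per cortical
    source; ``harmonic_amplitudes``/``harmonic_phases`` shape the source
    waveform; ``snr_db`` is the ratio of projected-source power to noise power
    per channel, in decibels.
    """

    subject_id: int
    mixing_matrix: np.ndarray
    harmonic_amplitudes: np.ndarray
    harmonic_phases: np.ndarray
    snr_db: float

    def __post_init__(self) -> None:
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=np.float64)
        self.harmonic_amplitudes = np.asarray(self.harmonic_amplitudes, dtype=np.float64)
        self.harmonic_phases = np.asarray(self.harmonic_phases, dtype=np.float64)
        if self.mixing_matrix.ndim != 2:
            raise InvalidConfigError("mixing_matrix must be 2-D")
        if np.any(self.harmonic_amplitudes < 0):
            raise InvalidConfigError("harmonic amplitudes must be non-negative")
        # an all-zero profile is allowed: it yields a pure-noise subject, the
        # natural null model for noise-floor checks

    @property
    def n_channels(self) -> int:
        return self.mixing_matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.mixing_matrix.shape[1]


@dataclass
class SimConfig:
    """Experiment-level simulation settings.

    Defaults mirror a Speller-style design: occipital 9-channel montage,
    250 Hz sampling, 5 s trials, 6 blocks.
    """

    n_subjects: int = 10
    n_blocks: int = 6
    stim_frequencies_hz: tuple[float, ...] = (10.0,)
    fs_hz: float = 250.0
    trial_duration_s: float = 5.0
    n_channels: int = 9
    n_sources: int = 2
    n_harmonics: int = 3
    harmonic_amplitudes: tuple[float, ...] = DEFAULT_HARMONIC_AMPLITUDES
    snr_db: float = 10.0
    noise_model: str = "white_plus_pink"
    subject_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise InvalidConfigError("need n_blocks >= 2 for block-wise evaluation")
        if not self.stim_frequencies_hz or any(f <= 0 for f in self.stim_frequencies_hz):
            raise InvalidConfigError("stimulation frequencies must be positive")
        if self.fs_hz <= 2.0 * max(self.stim_frequencies_hz) * self.n_harmonics:
            raise InvalidConfigError(
                "fs_hz must exceed twice the highest simulated harmonic "
                f"({max(self.stim_frequencies_hz)} Hz x {self.n_harmonics})"
            )
        if self.noise_model not in ("white", "white_plus_pink"):
            raise InvalidConfigError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.subject_separation <= 1.0:
            raise InvalidConfigError("subject_separation must be in [0, 1]")
        if len(self.harmonic_amplitudes) != self.n_harmonics:
            raise InvalidConfigError("harmonic_amplitudes length must equal n_harmonics")


def _random_unit_columns(rng: np.random.Generator, n_channels: int, n_sources: int) -> np.ndarray:
    """Gaussian matrix with columns normalized to unit Euclidean norm."""
    m = rng.standard_normal((n_channels, n_sources))
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def make_subject(
    seed: int,
    n_channels: int,
    n_sources: int,
    snr_db: float,
    subject_id: int = 1,
    harmonic_amplitudes: tuple[float, ...] = DEFAULT_HARMONIC_AMPLITUDES,
) -> SubjectModel:
    """Draw one subject: unit-column Gaussian mixing pattern + uniform phases."""
    if n_sources < 1 or n_sources > n_channels:
        raise InvalidConfigError(
            f"need 1 <= n_sources <= n_channels, got {n_sources} sources, "
            f"{n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    mixing = _random_unit_columns(rng, n_channels, n_sources)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(harmonic_amplitudes))
    return SubjectModel(
        subject_id=subject_id,
        mixing_matrix=mixing,
        harmonic_amplitudes=np.asarray(harmonic_amplitudes, dtype=np.float64),
        harmonic_phases=phases,
        snr_db=snr_db,
    )


def _source_signals(
    subject: SubjectModel, f_stim_hz: float, fs_hz: float, n_samples: int
) -> np.ndarray:
    """Harmonic sum per source, shape (n_sources, n_samples).

    Source k is lagged by a fixed phase offset pi*k/n_sources (scaled per
    harmonic) so that multiple sources are linearly independent in time.
    """
    t = np.arange(n_samples) / fs_hz
    h = np.arange(1, len(subject.harmonic_amplitudes) + 1)
    sources = np.zeros((subject.n_sources, n_samples))
    for k in range(subject.n_sources):
        psi = np.pi * k / subject.n_sources
        # (H, Nt) harmonic bank summed with the subject's amplitudes
        bank = np.sin(
            2.0 * np.pi * np.outer(h, f_stim_hz * t)
            + subject.harmonic_phases[:, None]
            + (h * psi)[:, None]
        )
        sources[k] = subject.harmonic_amplitudes @ bank
    return sources


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-shaped noise: white noise spectrally weighted by 1/sqrt(f), unit variance."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * weights, n=n, axis=1)
    std = pink.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return pink / std


def _noise(
    rng: np.random.Generator, shape: tuple[int, int], model: str
) -> np.ndarray:
    """Unit-variance noise matrix under the configured spectral model."""
    if model == "white":
        return rng.standard_normal(shape)
    # equal power split between white and 1/f components
    white = rng.standard_normal(shape)
    pink = _pink_noise(rng, shape)
    mix = (white + pink) / np.sqrt(2.0)
    return mix


def simulate_trial(
    subject: SubjectModel,
    f_stim_hz: float,
    config: SimConfig,
    rng: np.random.Generator,
    block_index: int = 1,
    channel_names: list[str] | None = None,
) -> Trial:
    """Generate one trial: ``X = mixing @ sources + noise``.

    Noise is scaled so the mean per-channel ratio of projected-source power to
    noise power equals ``subject.snr_db``.  An all-zero harmonic profile would
    make the SNR undefined, so such subjects produce pure noise at the noise
    power implied by unit signal power.
    """
    if not np.isfinite(f_stim_hz) or f_stim_hz <= 0:
        raise InvalidInputError(f"non-finite or non-positive stimulus frequency {f_stim_hz}")
    if not any(np.isclose(f_stim_hz, f) for f in config.stim_frequencies_hz):
        raise InvalidInputError(
            f"{f_stim_hz} Hz is not one of the configured stimulation frequencies"
        )
    if not np.isfinite(subject.snr_db):
        raise InvalidInputError("snr_db must be finite")
    n_samples = int(round(config.fs_hz * config.trial_duration_s))
    sources = _source_signals(subject, f_stim_hz, config.fs_hz, n_samples)
    clean = subject.mixing_matrix @ sources
    signal_power = float(np.mean(clean**2))
    if signal_power == 0.0:
        signal_power = 1.0
    noise_power = signal_power / (10.0 ** (subject.snr_db / 10.0))
    noise = _noise(rng, clean.shape, config.noise_model) * np.sqrt(noise_power)
    data = clean + noise
    data -= data.mean(axis=1, keepdims=True)
    if channel_names is None:
        channel_names = [f"CH{i + 1}" for i in range(config.n_channels)]
    return Trial(
        data=data,
        fs_hz=config.fs_hz,
        subject_id=subject.subject_id,
        block_index=block_index,
        stim_freq_hz=f_stim_hz,
        channel_names=channel_names,
    )


def _slerp_columns(unique: np.ndarray, base: np.ndarray, t: float) -> np.ndarray:
    """Column-wise spherical interpolation from `unique` (t=0) to `base` (t=1)."""
    out = np.empty_like(unique)
    for j in range(unique.shape[1]):
        u, v = unique[:, j], base[:, j]
        dot = float(np.clip(u @ v, -1.0, 1.0))
        omega = np.arccos(dot)
        if omega < 1e-12:
            out[:, j] = v
            continue
        out[:, j] = (np.sin((1.0 - t) * omega) * u + np.sin(t * omega) * v) / np.sin(omega)
    return out / np.linalg.norm(out, axis=0, keepdims=True)


def _subject_models(config: SimConfig) -> list[SubjectModel]:
    root = np.random.SeedSequence(config.seed)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    base = _random_unit_columns(base_rng, config.n_channels, config.n_sources)
    subjects = []
    for s in range(1, config.n_subjects + 1):
        child = np.random.SeedSequence(entropy=(config.seed, 1000 + s))
        rng = np.random.default_rng(child)
        unique = _random_unit_columns(rng, config.n_channels, config.n_sources)
        mixing = _slerp_columns(unique, base, config.subject_separation)
        if config.subject_separation >= 1.0:
            phases = np.zeros(config.n_harmonics)  # identical subjects share phases too
        else:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_harmonics)
        subjects.append(
            SubjectModel(
                subject_id=s,
                mixing_matrix=mixing,
                harmonic_amplitudes=np.asarray(config.harmonic_amplitudes),
                harmonic_phases=phases,
                snr_db=config.snr_db,
            )
        )
    return subjects


def simulate_dataset(config: SimConfig) -> TrialSet:
    """Full design: one trial per (subject, block, frequency) cell.

    Deterministic for a fixed config; the noise stream of each cell is seeded
    independently from (seed, subject, block, frequency index).
    """
    subjects = _subject_models(config)
    trials = []
    for subject in subjects:
        for block in range(1, config.n_blocks + 1):
            for fi, freq in enumerate(config.stim_frequencies_hz):
                cell_seed = np.random.SeedSequence(
                    entropy=(config.seed, subject.subject_id, block, fi)
                )
                rng = np.random.default_rng(cell_seed)
                trials.append(
                    simulate_trial(subject, freq, config, rng, block_index=block)
                )
    return TrialSet(
        trials=trials,
        n_subjects=config.n_subjects,
        n_blocks=config.n_blocks,
        frequencies=list(config.stim_frequencies_hz),
    )
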