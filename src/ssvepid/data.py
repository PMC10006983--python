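"""In-memory containers for multichannel EEG trials and trial collections.

A *trial* is one stimulus-locked EEG epoch: a channels x samples matrix plus
the metadata needed downstream (sampling rate, subject identity, block index,
stimulation frequency).  A *trial set* is the full experiment: one trial per
(subject, block, stimulation frequency) cell.  Rows are assumed centred
(band-pass filtering or detrending removes the mean in practice); the
preprocessing functions re-centre after filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["Trial", "TrialSet", "save_trialset", "load_trialset"]


@dataclass
class Trial:
    """One multichannel EEG epoch.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Microvolt-scale samples, one row per electrode.
    fs_hz : float
        Sampling rate in Hz.
    subject_id : int
        Identity label, 1-based.
    block_index : int
        Which repetition sweep the trial belongs to, 1-based.
    stim_freq_hz : float
        Flicker frequency of the visual stimulus.
    channel_names : list of str
        Electrode labels, one per row of ``data``.
    """

    data: np.ndarray
    fs_hz: float
    subject_id: int
    block_index: int
    stim_freq_hz: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidInputError(
                f"trial data must be 2-D (channels x samples), got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("trial data contains NaN or Inf")
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def with_data(self, data: np.ndarray, channel_names: list[str] | None = None) -> "Trial":
        """Copy of this trial with new samples (metadata preserved)."""
        kwargs = {"data": np.asarray(data, dtype=np.float64)}
        if channel_names is not None:
            kwargs["channel_names"] = list(channel_names)
        return replace(self, **kwargs)


@dataclass
class TrialSet:
    """A collection of trials spanning subjects, blocks and frequencies."""

    trials: list[Trial]
    n_subjects: int
    n_blocks: int
    frequencies: list[float]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def for_frequency(self, stim_freq_hz: float, rtol: float = 1e-9) -> "TrialSet":
        """Sub-set holding only trials at one stimulation frequency."""
        kept = [
            t
            for t in self.trials
            if np.isclose(t.stim_freq_hz, stim_freq_hz, rtol=rtol, atol=1e-9)
        ]
        return TrialSet(kept, self.n_subjects, self.n_blocks, [stim_freq_hz])

    def subject_ids(self) -> list[int]:
        return sorted({t.subject_id for t in self.trials})

    def block_indices(self) -> list[int]:
        return sorted({t.block_index for t in self.trials})


def save_trialset(trialset: TrialSet, path: str | Path) -> None:
    """Write a trial set as an ``.npz`` array container + JSON metadata sidecar.

    The ``.npz`` holds one array per trial (``trial_000000`` ...); the sidecar
    ``<path>.json`` records per-trial metadata and set-level counts.
    """
    path = Path(path)
    arrays = {f"trial_{i:06d}": t.data for i, t in enumerate(trialset.trials)}
    np.savez_compressed(path, **arrays)
    meta = {
        "format_version": "1",
        "n_subjects": trialset.n_subjects,
        "n_blocks": trialset.n_blocks,
        "frequencies": list(map(float, trialset.frequencies)),
        "trials": [
            {
                "key": f"trial_{i:06d}",
                "fs_hz": t.fs_hz,
                "subject_id": t.subject_id,
                "block_index": t.block_index,
                "stim_freq_hz": t.stim_freq_hz,
                "channel_names": t.channel_names,
            }
            for i, t in enumerate(trialset.trials)
        ],
    }
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix else path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def load_trialset(path: str | Path) -> TrialSet:
    """Inverse of :func:`save_trialset`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    with np.load(path) as arrays:
        trials = [
            Trial(
                data=arrays[m["key"]],
                fs_hz=m["fs_hz"],
                subject_id=m["subject_id"],
                block_index=m["block_index"],
                stim_freq_hz=m["stim_freq_hz"],
                channel_names=list(m["channel_names"]),
            )
            for m in meta["trials"]
        ]
    return TrialSet(
        trials=trials,
        n_subjects=meta["n_subjects"],
        n_blocks=meta["n_blocks"],
        frequencies=meta["frequencies"],
    )
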