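"""Best-effort loaders for the two public SSVEP benchmarks.

These adapt on-disk layouts to :class:`~ssvepid.data.Trial`/``TrialSet``:

* *Speller* benchmark (Tsinghua): one MAT v7.3 (HDF5) file per subject with a
  ``data`` array laid out channel x sample x block x target, 64 channels at
  250 Hz, 6 blocks, 40 targets from 8 to 15.8 Hz in 0.2 Hz steps.
* *EPOC* benchmark (PhysioNet ``mssvepdb``): 14-channel Emotiv recordings at
  128 Hz, 5 stimulation frequencies.

No data ships with the package; callers pass paths to their own downloads.
Layout details drift between dataset revisions, so treat these as adapters to
check against your copy rather than guaranteed parsers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import Trial, TrialSet
from .errors import InvalidInputError

__all__ = ["SPELLER_CHANNELS_64", "SPELLER_OCCIPITAL_9", "speller_frequencies", "load_speller_subject", "load_speller_dataset"]

#: The 64-channel montage of the Speller benchmark, in file order.
SPELLER_CHANNELS_64 = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F5", "F3", "F1", "Fz", "F2",
    "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "FT8", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "M1", "TP7",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "M2", "P7", "P5",
    "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "PO7", "PO5", "PO3", "POz",
    "PO4", "PO6", "PO8", "CB1", "O1", "Oz", "O2", "CB2",
]

#: Occipital / parietal-occipital subset used for identification.
SPELLER_OCCIPITAL_9 = ["Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2"]


def speller_frequencies() -> list[float]:
    """The 40 stimulation frequencies, 8–15.8 Hz in 0.2 Hz steps (row-major
    target order of the benchmark's frequency table)."""
    return [round(8.0 + 0.2 * k, 1) for k in range(40)]


def load_speller_subject(
    path: str | Path,
    subject_id: int,
    fs_hz: float = 250.0,
    channels: list[str] | None = None,
) -> list[Trial]:
    """Read one subject's MAT v7.3 file into trials.

    The stored array is channel x sample x block x target (64 x Nt x 6 x 40).
    ``channels`` (default: the 9 occipital/parietal-occipital electrodes)
    selects and orders rows.
    """
    import h5py

    channels = channels or SPELLER_OCCIPITAL_9
    freqs = speller_frequencies()
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise InvalidInputError(f"{path}: no 'data' array — not a Speller subject file?")
        raw = np.array(f["data"])
    # h5py exposes MATLAB arrays with reversed axis order
    if raw.ndim != 4:
        raise InvalidInputError(f"{path}: expected 4-D data, got shape {raw.shape}")
    if raw.shape[-1] != 64:
        raw = raw.transpose(3, 2, 1, 0)
    # now target x block x sample x channel
    idx = [SPELLER_CHANNELS_64.index(c) for c in channels]
    trials = []
    for target in range(raw.shape[0]):
        for block in range(raw.shape[1]):
            x = raw[target, block][:, idx].T  # channels x samples
            trials.append(
                Trial(
                    data=x,
                    fs_hz=fs_hz,
                    subject_id=subject_id,
                    block_index=block + 1,
                    stim_freq_hz=freqs[target],
                    channel_names=list(channels),
                )
            )
    return trials


def load_speller_dataset(
    directory: str | Path,
    n_subjects: int = 35,
    channels: list[str] | None = None,
) -> TrialSet:
    """Assemble ``S1.mat`` ... ``S<n>.mat`` from a directory into a TrialSet."""
    directory = Path(directory)
    trials = []
    for s in range(1, n_subjects + 1):
        path = directory / f"S{s}.mat"
        if not path.exists():
            raise InvalidInputError(f"missing subject file {path}")
        trials.extend(load_speller_subject(path, subject_id=s, channels=channels))
    n_blocks = max(t.block_index for t in trials)
    return TrialSet(
        trials=trials,
        n_subjects=n_subjects,
        n_blocks=n_blocks,
        frequencies=speller_frequencies(),
    )
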