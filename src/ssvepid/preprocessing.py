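"""Temporal filtering, filterbank expansion, channel selection and windowing.

All temporal filtering is zero-phase: a Butterworth band-pass applied
forward-backward (``scipy.signal.filtfilt``), so narrowband SSVEP components
keep their latency.  The pipeline order is fixed: filter the full-length
trial first, then cut the analysis window, so short windows are free of
filter edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import Trial
from .errors import (
    InvalidBandError,
    MissingChannelError,
    OutOfRangeWindowError,
    ShortTrialError,
)

__all__ = [
    "BandSpec",
    "FilterBank",
    "WindowSpec",
    "bandpass_zero_phase",
    "apply_filterbank",
    "window_trial",
    "select_channels",
    "default_filterbank",
]

#: Default analysis range (Hz) for a Speller-style montage.
DEFAULT_ANALYSIS_BAND = (8.0, 30.0)


@dataclass(frozen=True)
class BandSpec:
    """One pass-band, edges in Hz."""

    low_hz: float
    high_hz: float

    def validate(self, fs_hz: float) -> None:
        nyquist = fs_hz / 2.0
        if not 0.0 < self.low_hz < self.high_hz:
            raise InvalidBandError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= nyquist:
            raise InvalidBandError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({nyquist} Hz)"
            )


@dataclass(frozen=True)
class FilterBank:
    """An ordered set of band-pass filters sharing family and order."""

    bands: tuple[BandSpec, ...]
    order: int = 4
    filter_family: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self):
        if len(self.bands) < 1:
            raise InvalidBandError("filterbank needs at least one band")
        if self.filter_family != "butterworth":
            raise InvalidBandError(f"unsupported filter family {self.filter_family!r}")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def edges(self) -> list[tuple[float, float]]:
        return [(b.low_hz, b.high_hz) for b in self.bands]


def default_filterbank(
    low_hz: float = DEFAULT_ANALYSIS_BAND[0],
    high_hz: float = DEFAULT_ANALYSIS_BAND[1],
    n_bands: int = 4,
    order: int = 4,
) -> FilterBank:
    """Equal-width partition of the analysis range into ``n_bands`` sub-bands.

    With the defaults this yields (8-13.5, 13.5-19, 19-24.5, 24.5-30) Hz.
    """
    edges = np.linspace(low_hz, high_hz, n_bands + 1)
    bands = tuple(BandSpec(lo, hi) for lo, hi in zip(edges[:-1], edges[1:]))
    return FilterBank(bands=bands, order=order)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: keep ``tw_s`` seconds starting ``onset_offset_s`` in."""

    tw_s: float
    onset_offset_s: float = 0.0


def _butter_ba(band: BandSpec, fs_hz: float, order: int):
    return signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs_hz, output="ba"
    )


def bandpass_zero_phase(trial: Trial, band: BandSpec, order: int = 4) -> Trial:
    """Zero-phase Butterworth band-pass; rows re-centred afterwards.

    Forward-backward application doubles the effective order and cancels the
    phase response.  Edge handling uses filtfilt's odd-reflection padding of
    length 3*(order+1) coefficients.
    """
    band.validate(trial.fs_hz)
    b, a = _butter_ba(band, trial.fs_hz, order)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trial.n_samples <= padlen:
        raise ShortTrialError(
            f"trial of {trial.n_samples} samples too short for padding length {padlen}"
        )
    filtered = signal.filtfilt(b, a, trial.data, axis=1)
    filtered -= filtered.mean(axis=1, keepdims=True)
    return trial.with_data(filtered)


def apply_filterbank(trial: Trial, bank: FilterBank) -> list[Trial]:
    """Band-pass the trial through every band of the bank, in band order."""
    return [bandpass_zero_phase(trial, band, bank.order) for band in bank.bands]


def window_trial(trial: Trial, window: WindowSpec) -> Trial:
    """Cut the analysis window [offset, offset + tw) out of the trial."""
    if window.tw_s <= 0:
        raise OutOfRangeWindowError(f"window duration must be positive, got {window.tw_s}")
    start = int(round(window.onset_offset_s * trial.fs_hz))
    length = int(round(window.tw_s * trial.fs_hz))
    if start < 0 or start + length > trial.n_samples:
        raise OutOfRangeWindowError(
            f"window [{window.onset_offset_s}, {window.onset_offset_s + window.tw_s}) s "
            f"outside a {trial.duration_s} s trial"
        )
    return trial.with_data(trial.data[:, start : start + length])


def select_channels(trial: Trial, names: list[str]) -> Trial:
    """Subset and reorder rows to match ``names``."""
    missing = [n for n in names if n not in trial.channel_names]
    if missing:
        raise MissingChannelError(f"channels not present: {missing}")
    idx = [trial.channel_names.index(n) for n in names]
    return trial.with_data(trial.data[idx, :], channel_names=list(names))
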