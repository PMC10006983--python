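"""Filterbank common spatial patterns (FBCSP) for person identification.

Common spatial patterns find channel-weight vectors ``w`` extremizing the
variance ratio

    J(w) = (w' C1 w) / (w' C2 w)

between two conditions, where ``Ci`` is the class covariance in one
filterbank band.  Maximizing J subject to ``w' C2 w = 1`` is the generalized
eigenproblem ``C1 w = lambda C2 w``; classification uses eigenvectors from
both ends of the spectrum (the ``p`` largest and ``p`` smallest eigenvalues,
2p filters per problem).  Identification is multiclass, handled one-vs-rest:
one CSP problem per person against the pooled remaining persons, per band.
The feature vector of a trial is the natural log of the variance of each
spatially filtered "virtual channel", concatenated class-major, then band,
then filter column — a vector of length ``Np * B * 2p``.

Covariances are trace-normalized per trial, averaged over trials, and
stabilized with a small diagonal loading; variance uses the population
(1/Nt) convention consistent with the trace-normalized estimator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .data import Trial, TrialSet
from .errors import (
    DegenerateTrialError,
    InvalidConfigError,
    InvalidInputError,
    InvalidTrainingSetError,
)
from .preprocessing import BandSpec, FilterBank, WindowSpec, apply_filterbank, window_trial

__all__ = [
    "ClassCovariances",
    "CSPModel",
    "FeatureVector",
    "FeatureScaler",
    "spatial_covariance",
    "class_covariance",
    "csp_pair",
    "fit_fbcsp_ovr",
    "extract_features",
    "csp_objective",
    "log_variances",
]

logger = logging.getLogger(__name__)

#: Default diagonal-loading weight for class covariances.
DEFAULT_SHRINKAGE = 1e-6
#: Condition-number ceiling above which the loading is raised automatically.
CONDITION_LIMIT = 1e10
#: Floor for zero-variance projections before taking the log.
LOG_VARIANCE_EPS = 1e-12


@dataclass
class ClassCovariances:
    """The covariance pair of one one-vs-rest problem in one band."""

    c1: np.ndarray
    c2: np.ndarray
    band_index: int = 0
    class_index: int = 0


@dataclass
class FeatureVector:
    """One trial's FBCSP log-variance features plus its identity label."""

    values: np.ndarray
    subject_label: int
    block_index: int = 0
    stim_freq_hz: float = 0.0
    clamped: bool = False  # True if any projection hit the zero-variance floor


def spatial_covariance(trial: Trial) -> np.ndarray:
    """Trace-normalized spatial covariance ``X X' / trace(X X')``.

    Rows are centred first so the estimate is a covariance rather than a raw
    second moment.  Output is symmetric PSD with unit trace.
    """
    x = trial.data - trial.data.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise DegenerateTrialError("zero-power trial: covariance undefined")
    c /= tr
    return 0.5 * (c + c.T)


def class_covariance(
    trials: list[Trial], shrinkage: float = DEFAULT_SHRINKAGE
) -> np.ndarray:
    """Mean of per-trial normalized covariances with diagonal loading.

    Loading replaces ``C`` by ``(1-g) C + g (trace(C)/Nch) I``; with unit-trace
    inputs this shrinks toward ``I/Nch``, and ``g=1`` returns exactly that.
    """
    if not trials:
        raise InvalidInputError("empty trial list")
    n_ch = trials[0].n_channels
    if any(t.n_channels != n_ch for t in trials):
        raise InvalidInputError("trials disagree on channel count")
    c = np.mean([spatial_covariance(t) for t in trials], axis=0)
    return (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n_ch) * np.eye(n_ch)


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive (sign convention)."""
    idx = np.argmax(np.abs(w), axis=0)
    signs = np.sign(w[idx, np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    return w * signs


def csp_pair(cov: ClassCovariances, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``C1 w = lambda C2 w`` and keep the 2p extremal eigenvectors.

    Returns ``(W, eigenvalues)`` where ``W`` is ``Nch x 2p`` — first the p
    eigenvectors of the largest eigenvalues (descending), then the p of the
    smallest (ascending order of position, i.e. still descending eigenvalue) —
    and ``eigenvalues`` is the full spectrum sorted descending.  Columns
    satisfy ``w' C2 w = 1``.
    """
    n_ch = cov.c1.shape[0]
    if 2 * p > n_ch:
        raise InvalidConfigError(f"2p={2 * p} filters exceed {n_ch} channels")
    c2 = cov.c2
    cond = np.linalg.cond(c2)
    if cond > CONDITION_LIMIT:
        logger.warning(
            "c2 condition number %.3g exceeds %.1g; raising diagonal loading",
            cond,
            CONDITION_LIMIT,
        )
        c2 = 0.999 * c2 + 1e-3 * (np.trace(c2) / n_ch) * np.eye(n_ch)
    # scipy.linalg.eigh returns ascending eigenvalues with V' C2 V = I,
    # which is exactly the w' C2 w = 1 normalization.
    eigvals, eigvecs = linalg.eigh(cov.c1, c2)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = np.concatenate([np.arange(p), np.arange(n_ch - p, n_ch)])
    w = _fix_sign(eigvecs[:, keep])
    return w, eigvals


def csp_objective(w: np.ndarray, c1: np.ndarray, c2: np.ndarray) -> float:
    """The CSP variance-ratio objective J(w) for a single filter."""
    return float((w @ c1 @ w) / (w @ c2 @ w))


def log_variances(z: np.ndarray) -> tuple[np.ndarray, bool]:
    """Natural log of the population (1/Nt) variance of each column of ``z``.

    Zero-variance columns are clamped at ``log(1e-12)``; the flag reports
    whether any clamping occurred.
    """
    var = np.atleast_2d(z).var(axis=0)
    low = var < LOG_VARIANCE_EPS
    if np.any(low):
        var = np.where(low, LOG_VARIANCE_EPS, var)
    return np.log(var), bool(np.any(low))


def _band_windowed(trial: Trial, bank: FilterBank, window: WindowSpec | None) -> list[Trial]:
    """Filter full-length trial per band, then window (fixed pipeline order)."""
    banded = apply_filterbank(trial, bank)
    if window is not None:
        banded = [window_trial(t, window) for t in banded]
    return banded


@dataclass
class CSPModel:
    """Fitted one-vs-rest FBCSP model.

    ``filters[(class_index, band_index)]`` holds the ``Nch x 2p`` spatial
    filter matrix of that one-vs-rest problem; ``eigenvalues`` the matching
    full descending spectra.  ``classes`` maps class index (0-based position)
    to subject label.
    """

    bands: FilterBank
    p: int
    filters: dict[tuple[int, int], np.ndarray]
    eigenvalues: dict[tuple[int, int], np.ndarray]
    classes: list[int]
    channel_names: list[str] = field(default_factory=list)
    window: WindowSpec | None = None
    format_version: str = "1"

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def feature_dim(self) -> int:
        return self.n_classes * self.bands.n_bands * 2 * self.p

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive (lossless round-trip)."""
        path = Path(path)
        meta = {
            "format_version": self.format_version,
            "band_edges": self.bands.edges(),
            "filter_order": self.bands.order,
            "p": self.p,
            "classes": self.classes,
            "channel_names": self.channel_names,
            "window": None
            if self.window is None
            else [self.window.tw_s, self.window.onset_offset_s],
        }
        arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for (ci, bi), w in self.filters.items():
            arrays[f"W_{ci}_{bi}"] = w
            arrays[f"L_{ci}_{bi}"] = self.eigenvalues[(ci, bi)]
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CSPModel":
        with np.load(path) as arrays:
            meta = json.loads(bytes(arrays["_meta"]).decode())
            filters, eigenvalues = {}, {}
            for key in arrays.files:
                if key.startswith("W_"):
                    _, ci, bi = key.split("_")
                    filters[(int(ci), int(bi))] = arrays[key]
                elif key.startswith("L_"):
                    _, ci, bi = key.split("_")
                    eigenvalues[(int(ci), int(bi))] = arrays[key]
        bank = FilterBank(
            bands=tuple(BandSpec(lo, hi) for lo, hi in meta["band_edges"]),
            order=meta["filter_order"],
        )
        window = None if meta["window"] is None else WindowSpec(*meta["window"])
        return cls(
            bands=bank,
            p=meta["p"],
            filters=filters,
            eigenvalues=eigenvalues,
            classes=list(meta["classes"]),
            channel_names=list(meta["channel_names"]),
            window=window,
            format_version=meta["format_version"],
        )


def fit_fbcsp_ovr(
    trainset: TrialSet,
    bank: FilterBank,
    p: int = 2,
    window: WindowSpec | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> CSPModel:
    """Fit one-vs-rest FBCSP filters: one GEVD per (person, band).

    For each person, ``C1`` averages that person's band-filtered trial
    covariances and ``C2`` the pooled covariances of everyone else.  Trials
    must all share one stimulation frequency (identification compares
    responses to the *same* flicker).
    """
    trials = list(trainset.trials)
    if not trials:
        raise InvalidTrainingSetError("empty training set")
    freqs = {round(t.stim_freq_hz, 6) for t in trials}
    if len(freqs) > 1:
        raise InvalidTrainingSetError(
            f"training trials span several stimulation frequencies: {sorted(freqs)}"
        )
    classes = sorted({t.subject_id for t in trials})
    if len(classes) < 2:
        raise InvalidTrainingSetError("need at least two subjects")
    by_subject: dict[int, list[Trial]] = {c: [] for c in classes}
    for t in trials:
        by_subject[t.subject_id].append(t)
    if any(len(v) == 0 for v in by_subject.values()):
        raise InvalidTrainingSetError("a subject has no trials")

    # filter (and window) every trial once per band, cache by band
    banded: dict[int, dict[int, list[np.ndarray]]] = {
        bi: {c: [] for c in classes} for bi in range(bank.n_bands)
    }
    cov_cache: dict[int, dict[int, list[np.ndarray]]] = {
        bi: {c: [] for c in classes} for bi in range(bank.n_bands)
    }
    for c in classes:
        for t in by_subject[c]:
            for bi, bt in enumerate(_band_windowed(t, bank, window)):
                cov_cache[bi][c].append(spatial_covariance(bt))

    def loaded_mean(covs: list[np.ndarray]) -> np.ndarray:
        n_ch = covs[0].shape[0]
        c = np.mean(covs, axis=0)
        return (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n_ch) * np.eye(n_ch)

    filters: dict[tuple[int, int], np.ndarray] = {}
    eigenvalues: dict[tuple[int, int], np.ndarray] = {}
    for ci, c in enumerate(classes):
        for bi in range(bank.n_bands):
            own = cov_cache[bi][c]
            rest = [cv for other in classes if other != c for cv in cov_cache[bi][other]]
            cov = ClassCovariances(
                c1=loaded_mean(own), c2=loaded_mean(rest), band_index=bi, class_index=ci
            )
            w, lam = csp_pair(cov, p)
            filters[(ci, bi)] = w
            eigenvalues[(ci, bi)] = lam

    return CSPModel(
        bands=bank,
        p=p,
        filters=filters,
        eigenvalues=eigenvalues,
        classes=classes,
        channel_names=list(trials[0].channel_names),
        window=window,
    )


def extract_features(trial: Trial, model: CSPModel) -> FeatureVector:
    """FBCSP log-variance features of one trial under a fitted model.

    The trial is band-filtered with the model's bank (then windowed if the
    model was fitted with a window); for each (class, band) the spatially
    filtered trial ``Z = X(b)' W`` yields ``2p`` virtual channels whose
    population variances enter as natural logs.  Zero-variance projections
    are clamped at ``log(1e-12)`` and flagged.
    """
    if model.channel_names and trial.channel_names:
        if trial.n_channels != len(model.channel_names):
            raise InvalidInputError(
                f"trial has {trial.n_channels} channels, model expects "
                f"{len(model.channel_names)}"
            )
    banded = _band_windowed(trial, model.bands, model.window)
    parts = []
    clamped = False
    for ci in range(model.n_classes):
        for bi in range(model.bands.n_bands):
            w = model.filters[(ci, bi)]
            x = banded[bi].data
            z = x.T @ w  # Nt x 2p
            logv, hit_floor = log_variances(z)
            clamped = clamped or hit_floor
            parts.append(logv)
    values = np.concatenate(parts)
    assert values.shape[0] == model.feature_dim
    return FeatureVector(
        values=values,
        subject_label=trial.subject_id,
        block_index=trial.block_index,
        stim_freq_hz=trial.stim_freq_hz,
        clamped=clamped,
    )


@dataclass
class FeatureScaler:
    """Per-dimension z-scoring with training-fold statistics.

    The same standardization feeds the DFN and the distance/margin-based
    baselines so the comparison is on features, not on scaling.
    """

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise InvalidInputError("scaler not fitted")
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.std_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y) arrays."""
    x = np.stack([f.values for f in features])
    y = np.array([f.subject_label for f in features])
    return x, y
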