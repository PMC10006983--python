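"""Evaluation machinery: leave-one-block-out folds, CRR, usability U, sweeps.

Identification accuracy is the *correct recognition rate* (CRR): the mean of
the diagonal of the row-normalized confusion matrix, in percent — balanced
per-class recall, which coincides with plain accuracy in the balanced
block design.  Per frequency, CRR is computed on the confusion matrix pooled
over all leave-one-block-out folds.

System-level practicality is summarized by the usability measure

    U = N * CRR / (Tr + K * Te)

with N subjects, K electrodes, Tr seconds of training EEG and Te seconds of
test EEG: high recognition from short recordings and few electrodes scores
highest.  ``Tr`` defaults to 25 s (five training blocks of 5 s trials in a
Speller-style six-block design) and is configurable.

A classical one-way ANOVA (with pairwise Welch t-tests under Bonferroni
correction as the post hoc reading) is provided for method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BaselineConfig, KNNClassifier, LinearSVMClassifier
from .data import TrialSet
from .dfn import DFNClassifier, DFNConfig
from .errors import IncompleteDesignError, InvalidConfigError, InvalidInputError
from .fbcsp import FeatureScaler, extract_features, feature_matrix, fit_fbcsp_ovr
from .preprocessing import FilterBank, WindowSpec, default_filterbank

__all__ = [
    "FoldResult",
    "UsabilityParams",
    "PredictionSet",
    "lobo_folds",
    "crr",
    "usability",
    "run_lobo",
    "sweep_tw",
    "one_way_anova",
    "pairwise_welch",
    "make_classifier",
    "DEFAULT_TRAIN_DURATION_S",
]

#: Default training-set duration entering U (five 5-s training blocks).
DEFAULT_TRAIN_DURATION_S = 25.0


@dataclass
class FoldResult:
    confusion_matrix: np.ndarray
    crr_percent: float
    fold_index: int
    stim_freq_hz: float
    tw_s: float


@dataclass
class UsabilityParams:
    n_subjects: int
    n_electrodes: int
    crr_percent: float
    train_duration_s: float = DEFAULT_TRAIN_DURATION_S
    test_duration_s: float = 5.0


@dataclass
class PredictionSet:
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    probabilities: np.ndarray | None = None

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels)
        self.predicted_labels = np.asarray(self.predicted_labels)
        if len(self.true_labels) != len(self.predicted_labels):
            raise InvalidInputError("true/predicted label lengths differ")


def lobo_folds(trialset: TrialSet, stim_freq: float) -> list[tuple[TrialSet, TrialSet]]:
    """Leave-one-block-out folds at one stimulation frequency.

    Fold k holds out block k: its test set is exactly one trial per subject;
    the training set is every other block.  A missing (subject, block) cell
    is an error — the design must be complete.
    """
    subset = trialset.for_frequency(stim_freq)
    if not subset.trials:
        raise InvalidInputError(f"no trials at {stim_freq} Hz")
    subjects = subset.subject_ids()
    blocks = subset.block_indices()
    cell: dict[tuple[int, int], list] = {}
    for t in subset.trials:
        cell.setdefault((t.subject_id, t.block_index), []).append(t)
    for s in subjects:
        for b in blocks:
            if (s, b) not in cell:
                raise IncompleteDesignError(f"subject {s} missing from block {b}")
    folds = []
    for b in blocks:
        test = [t for t in subset.trials if t.block_index == b]
        train = [t for t in subset.trials if t.block_index != b]
        folds.append(
            (
                TrialSet(train, subset.n_subjects, subset.n_blocks, [stim_freq]),
                TrialSet(test, subset.n_subjects, subset.n_blocks, [stim_freq]),
            )
        )
    return folds


def confusion(pred: PredictionSet, classes: list[int]) -> np.ndarray:
    """Integer confusion matrix, rows = true class, in the order of ``classes``."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for yt, yp in zip(pred.true_labels, pred.predicted_labels):
        cm[index[int(yt)], index[int(yp)]] += 1
    return cm


def crr(pred: PredictionSet, n_classes: int | None = None) -> float:
    """Correct recognition rate (%): mean diagonal of the row-normalized
    confusion matrix."""
    if len(pred.true_labels) == 0:
        raise InvalidInputError("empty prediction set")
    classes = sorted(set(pred.true_labels.tolist()) | set(pred.predicted_labels.tolist()))
    if n_classes is not None and len(set(pred.true_labels.tolist())) < n_classes:
        raise InvalidInputError(
            "a class has zero true instances; its recall (confusion row) is undefined"
        )
    cm = confusion(pred, classes)
    row_sums = cm.sum(axis=1)
    present = row_sums > 0
    if not np.all(present):
        raise InvalidInputError("a class has zero true instances")
    recalls = cm.diagonal()[present] / row_sums[present]
    return 100.0 * float(np.mean(recalls))


def usability(params: UsabilityParams) -> float:
    """U = N * CRR / (Tr + K * Te), with CRR on the percent scale."""
    denom = params.train_duration_s + params.n_electrodes * params.test_duration_s
    if denom <= 0:
        raise InvalidConfigError("non-positive usability denominator")
    return params.n_subjects * params.crr_percent / denom


def make_classifier(name: str, seed: int = 0, **kwargs):
    """Factory for the three classifiers behind one fit/predict surface."""
    if name == "dfn":
        cfg = kwargs.pop("config", None) or DFNConfig(seed=seed, **kwargs)
        return DFNClassifier(cfg)
    if name == "svm":
        return LinearSVMClassifier(kwargs.pop("config", None) or BaselineConfig(**kwargs))
    if name == "knn":
        return KNNClassifier(kwargs.pop("config", None) or BaselineConfig(**kwargs))
    raise InvalidConfigError(f"unknown classifier {name!r} (expected dfn|svm|knn)")


def run_lobo(
    trialset: TrialSet,
    stim_freq: float,
    bank: FilterBank | None = None,
    p: int = 2,
    classifier: str = "dfn",
    seed: int = 0,
    tw_s: float | None = None,
    onset_offset_s: float = 0.0,
    classifier_kwargs: dict | None = None,
) -> tuple[float, list[FoldResult]]:
    """Full pipeline under leave-one-block-out at one frequency.

    Per fold: fit one-vs-rest FBCSP on the training blocks, extract and
    z-score features with training statistics, train the classifier, predict
    the held-out block.  Returns the pooled-confusion CRR (%) and per-fold
    results.
    """
    bank = bank or default_filterbank()
    window = None if tw_s is None else WindowSpec(tw_s=tw_s, onset_offset_s=onset_offset_s)
    folds = lobo_folds(trialset, stim_freq)
    classes = trialset.for_frequency(stim_freq).subject_ids()
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    fold_results = []
    all_true, all_pred = [], []
    for k, (train, test) in enumerate(folds):
        model = fit_fbcsp_ovr(train, bank, p=p, window=window)
        train_feats = [extract_features(t, model) for t in train.trials]
        test_feats = [extract_features(t, model) for t in test.trials]
        x_tr, y_tr = feature_matrix(train_feats)
        x_te, y_te = feature_matrix(test_feats)
        scaler = FeatureScaler()
        x_tr = scaler.fit_transform(x_tr)
        x_te = scaler.transform(x_te)
        blocks = np.array([f.block_index for f in train_feats])
        clf = make_classifier(classifier, seed=seed, **(classifier_kwargs or {}))
        clf.fit(x_tr, y_tr, blocks=blocks)
        y_hat = clf.predict(x_te)
        pred = PredictionSet(y_te, y_hat)
        cm = confusion(pred, classes)
        pooled += cm
        fold_results.append(
            FoldResult(
                confusion_matrix=cm,
                crr_percent=100.0 * float(np.mean(cm.diagonal() / cm.sum(axis=1))),
                fold_index=k,
                stim_freq_hz=stim_freq,
                tw_s=tw_s if tw_s is not None else trialset.trials[0].duration_s,
            )
        )
        all_true.extend(y_te.tolist())
        all_pred.extend(np.asarray(y_hat).tolist())
    pooled_crr = crr(PredictionSet(np.array(all_true), np.array(all_pred)))
    return pooled_crr, fold_results


def sweep_tw(
    trialset: TrialSet,
    tws: list[float],
    classifier: str = "dfn",
    bank: FilterBank | None = None,
    p: int = 2,
    seed: int = 0,
    classifier_kwargs: dict | None = None,
) -> pd.DataFrame:
    """CRR averaged over stimulation frequencies for each window length TW."""
    rows = []
    for tw in tws:
        crrs = []
        for freq in trialset.frequencies:
            pooled_crr, _ = run_lobo(
                trialset,
                freq,
                bank=bank,
                p=p,
                classifier=classifier,
                seed=seed,
                tw_s=tw,
                classifier_kwargs=classifier_kwargs,
            )
            crrs.append(pooled_crr)
        rows.append({"tw_s": tw, "mean_crr_percent": float(np.mean(crrs))})
    return pd.DataFrame(rows)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p).

    Zero within-group variance with unequal means reports F = +inf, p = 0;
    identical groups report F = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    n = sum(len(g) for g in groups)
    g = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df_b, df_w = g - 1, n - g
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df_b, df_w, 1.0
        return float("inf"), df_b, df_w, 0.0
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), df_b, df_w, p


def pairwise_welch(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Post hoc reading: pairwise Welch t-tests with Bonferroni correction."""
    names = list(groups)
    n_tests = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonferroni": min(1.0, float(p) * n_tests),
                }
            )
    return pd.DataFrame(rows)
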