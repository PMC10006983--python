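"""End-to-end orchestration: enrollment, authentication, benchmark sweeps.

The identification system has two phases.  *Enrollment* takes labelled
trials, learns the one-vs-rest FBCSP spatial filters, extracts and
standardizes features, trains the classifier, and persists three artifacts —
the spatial-filter model, the trained classifier, and the feature store —
plus a manifest recording the config hash and seed.  *Authentication* loads
those artifacts and assigns an identity (with class probabilities) to new
trials without retraining.  ``run_benchmark`` drives the full LOBO sweeps
and emits CRR-per-frequency, CRR-per-TW and U-per-TW tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import TrialSet, load_trialset
from .dfn import DFNClassifier, DFNConfig, DFNModel
from .baselines import BaselineConfig, KNNClassifier, LinearSVMClassifier
from .errors import (
    InvalidConfigError,
    NotEnrolledError,
    PipelineStageError,
    SSVEPIDError,
)
from .evaluation import (
    DEFAULT_TRAIN_DURATION_S,
    PredictionSet,
    UsabilityParams,
    crr,
    make_classifier,
    run_lobo,
    usability,
)
from .fbcsp import (
    CSPModel,
    FeatureScaler,
    extract_features,
    feature_matrix,
    fit_fbcsp_ovr,
)
from .preprocessing import FilterBank, BandSpec, WindowSpec, default_filterbank
from .synthetic import SimConfig, simulate_dataset

__all__ = ["RunConfig", "run_enrollment", "run_authentication", "run_benchmark"]

logger = logging.getLogger(__name__)

ARTIFACT_CSP = "csp_model.npz"
ARTIFACT_CLF = "classifier.npz"
ARTIFACT_FEATURES = "features.npz"
MANIFEST = "manifest.json"


@dataclass
class RunConfig:
    """One experiment: data source, preprocessing, features, classifier, eval."""

    simulation: SimConfig = field(default_factory=SimConfig)
    dataset_path: str | None = None  # overrides simulation when set
    filterbank_edges: list[tuple[float, float]] | None = None
    filter_order: int = 4
    channels: list[str] | None = None
    tw_s: float | None = None
    onset_offset_s: float = 0.0
    p: int = 2
    classifier: str = "dfn"
    dfn: DFNConfig = field(default_factory=DFNConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    tw_list: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.5, 5.0])
    train_duration_s: float = DEFAULT_TRAIN_DURATION_S
    seed: int = 0
    output_dir: str = "results"
    profile: str = "quick"  # quick | full-scale

    def __post_init__(self):
        if self.classifier not in ("dfn", "svm", "knn"):
            raise InvalidConfigError(f"unknown classifier {self.classifier!r}")
        if self.profile not in ("quick", "full-scale"):
            raise InvalidConfigError(f"unknown profile {self.profile!r}")
        # one seed drives every stochastic component
        self.simulation.seed = self.seed
        self.dfn.seed = self.seed

    def bank(self) -> FilterBank:
        if self.filterbank_edges is None:
            return default_filterbank(order=self.filter_order)
        return FilterBank(
            bands=tuple(BandSpec(lo, hi) for lo, hi in self.filterbank_edges),
            order=self.filter_order,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["stim_frequencies_hz"] = list(
            d["simulation"]["stim_frequencies_hz"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "stim_frequencies_hz" in sim:
                sim["stim_frequencies_hz"] = tuple(sim["stim_frequencies_hz"])
            if "harmonic_amplitudes" in sim:
                sim["harmonic_amplitudes"] = tuple(sim["harmonic_amplitudes"])
            d["simulation"] = SimConfig(**sim)
        if "dfn" in d and isinstance(d["dfn"], dict):
            dfn = dict(d["dfn"])
            if "hidden_dims" in dfn:
                dfn["hidden_dims"] = tuple(dfn["hidden_dims"])
            if "blocks_kept" in dfn:
                dfn["blocks_kept"] = tuple(dfn["blocks_kept"])
            d["dfn"] = DFNConfig(**dfn)
        if "baseline" in d and isinstance(d["baseline"], dict):
            d["baseline"] = BaselineConfig(**d["baseline"])
        if "filterbank_edges" in d and d["filterbank_edges"] is not None:
            d["filterbank_edges"] = [tuple(e) for e in d["filterbank_edges"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-ish context: re-raise stage errors with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage=%s duration=%.3fs", name, dt)
                return False
            if isinstance(exc, PipelineStageError):
                return False
            raise PipelineStageError(name, exc) from exc

    return _Ctx()


def _load_or_simulate(config: RunConfig) -> TrialSet:
    if config.dataset_path is not None:
        path = Path(config.dataset_path)
        if not path.exists():
            raise InvalidConfigError(f"dataset path {path} does not exist")
        return load_trialset(path)
    return simulate_dataset(config.simulation)


def _classifier_for(config: RunConfig, seed: int):
    if config.classifier == "dfn":
        return make_classifier("dfn", config=config.dfn)
    return make_classifier(config.classifier, config=config.baseline)


def run_enrollment(config: RunConfig, trialset: TrialSet | None = None) -> dict:
    """Train and persist the three enrollment artifacts + manifest.

    Returns the manifest dict (artifact names, config hash, seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage("load_data"):
        trialset = trialset if trialset is not None else _load_or_simulate(config)
        freq = trialset.frequencies[0]
        subset = trialset.for_frequency(freq)
    window = (
        None if config.tw_s is None else WindowSpec(config.tw_s, config.onset_offset_s)
    )
    with _stage("fit_csp"):
        csp = fit_fbcsp_ovr(subset, config.bank(), p=config.p, window=window)
        csp.save(out / ARTIFACT_CSP)
    with _stage("extract_features"):
        feats = [extract_features(t, csp) for t in subset.trials]
        x, y = feature_matrix(feats)
        scaler = FeatureScaler()
        xs = scaler.fit_transform(x)
        np.savez(
            out / ARTIFACT_FEATURES,
            features=x,
            labels=y,
            blocks=np.array([f.block_index for f in feats]),
            scaler_mean=scaler.mean_,
            scaler_std=scaler.std_,
        )
    with _stage("train_classifier"):
        clf = _classifier_for(config, config.seed)
        clf.fit(xs, y, blocks=np.array([f.block_index for f in feats]))
        if isinstance(clf, DFNClassifier):
            clf.model.save(out / ARTIFACT_CLF)
        else:
            # baselines are cheap to refit; persist their training data + config
            np.savez(
                out / ARTIFACT_CLF,
                kind=np.frombuffer(config.classifier.encode(), dtype=np.uint8),
                x=xs,
                y=y,
            )
    manifest = {
        "artifacts": [ARTIFACT_CSP, ARTIFACT_CLF, ARTIFACT_FEATURES],
        "classifier": config.classifier,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stim_freq_hz": float(freq),
    }
    (out / MANIFEST).write_text(json.dumps(manifest, indent=1))
    logger.info("enrollment complete: %s", out)
    return manifest


def run_authentication(config: RunConfig, trials) -> pd.DataFrame:
    """Identify each trial with the stored artifacts; never retrains."""
    out = Path(config.output_dir)
    manifest_path = out / MANIFEST
    if not manifest_path.exists():
        raise NotEnrolledError(f"no enrollment manifest in {out}")
    manifest = json.loads(manifest_path.read_text())
    for name in manifest["artifacts"]:
        if not (out / name).exists():
            raise NotEnrolledError(f"missing enrollment artifact {name}")
    try:
        csp = CSPModel.load(out / ARTIFACT_CSP)
        store = np.load(out / ARTIFACT_FEATURES)
        scaler = FeatureScaler(mean_=store["scaler_mean"], std_=store["scaler_std"])
    except Exception as exc:  # corrupt artifact
        raise NotEnrolledError(f"corrupt enrollment artifacts in {out}: {exc}") from exc
    with _stage("extract_features"):
        feats = [extract_features(t, csp) for t in trials]
        x, y_true = feature_matrix(feats)
        xs = scaler.transform(x)
    with _stage("predict"):
        kind = manifest["classifier"]
        if kind == "dfn":
            model = DFNModel.load(out / ARTIFACT_CLF)
            from .dfn import predict as dfn_predict

            labels, probs = dfn_predict(model, xs)
            top_p = probs.max(axis=1)
        else:
            blob = np.load(out / ARTIFACT_CLF)
            clf = _classifier_for(config, config.seed)
            clf.fit(blob["x"], blob["y"])
            labels = clf.predict(xs)
            top_p = np.full(len(labels), np.nan)
    return pd.DataFrame(
        {
            "true_subject": y_true,
            "predicted_subject": labels,
            "probability": top_p,
        }
    )


def run_benchmark(
    config: RunConfig,
    classifiers: tuple[str, ...] = ("dfn", "svm", "knn"),
    trialset: TrialSet | None = None,
) -> dict[str, pd.DataFrame]:
    """LOBO sweeps: CRR per frequency, CRR per TW, U per TW, per classifier.

    Writes three CSVs plus a JSON summary under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage("load_data"):
        trialset = trialset if trialset is not None else _load_or_simulate(config)
    bank = config.bank()
    n_ch = trialset.trials[0].n_channels
    full_tw = trialset.trials[0].duration_s

    freq_rows = []
    with _stage("crr_per_frequency"):
        for freq in trialset.frequencies:
            row = {"frequency_hz": freq}
            for name in classifiers:
                cfg_kwargs = (
                    {"config": config.dfn} if name == "dfn" else {"config": config.baseline}
                )
                pooled, _ = run_lobo(
                    trialset,
                    freq,
                    bank=bank,
                    p=config.p,
                    classifier=name,
                    seed=config.seed,
                    classifier_kwargs=cfg_kwargs,
                )
                row[name] = pooled
            freq_rows.append(row)
    per_freq = pd.DataFrame(freq_rows)

    tw_rows, u_rows = [], []
    with _stage("crr_per_tw"):
        for tw in config.tw_list:
            row = {"tw_s": tw}
            u_row = {"tw_s": tw}
            for name in classifiers:
                cfg_kwargs = (
                    {"config": config.dfn} if name == "dfn" else {"config": config.baseline}
                )
                crrs = []
                for freq in trialset.frequencies:
                    pooled, _ = run_lobo(
                        trialset,
                        freq,
                        bank=bank,
                        p=config.p,
                        classifier=name,
                        seed=config.seed,
                        tw_s=None if tw >= full_tw else tw,
                        classifier_kwargs=cfg_kwargs,
                    )
                    crrs.append(pooled)
                mean_crr = float(np.mean(crrs))
                row[name] = mean_crr
                u_row[name] = usability(
                    UsabilityParams(
                        n_subjects=trialset.n_subjects,
                        n_electrodes=n_ch,
                        crr_percent=mean_crr,
                        train_duration_s=config.train_duration_s,
                        test_duration_s=tw,
                    )
                )
            tw_rows.append(row)
            u_rows.append(u_row)
    per_tw = pd.DataFrame(tw_rows)
    u_per_tw = pd.DataFrame(u_rows)

    per_freq.to_csv(out / "crr_per_frequency.csv", index=False)
    per_tw.to_csv(out / "crr_per_tw.csv", index=False)
    u_per_tw.to_csv(out / "usability_per_tw.csv", index=False)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "classifiers": list(classifiers),
        "mean_crr_full_tw": {
            name: float(per_freq[name].mean()) for name in classifiers
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"crr_per_frequency": per_freq, "crr_per_tw": per_tw, "usability_per_tw": u_per_tw}
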