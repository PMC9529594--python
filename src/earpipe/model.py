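"""Imbalance-aware training and cross-session evaluation.

Jaw-clench epochs are rare (< 10% of a session), so the training pipeline is
built around class imbalance: SMOTE oversampling of the minority class,
z-standardization fitted on training data only, a boosted-stump (AdaBoost)
classifier, stratified k-fold cross-validation for hyperparameter selection,
and precision/recall/F1/MCC as the metric suite. Evaluation is
cross-session: the model trains on pooled sessions and is scored on a fully
held-out session, the hard generalisation setting a wearable detector faces.

The module exposes both the individual operations (:func:`smote_oversample`,
:func:`zstandardize`, :func:`train_classifier`, :func:`stratified_cv`,
:func:`evaluate`) and a statsmodels-style pair — :class:`BruxismModel`
(construct from feature matrices or raw sessions, then ``fit()``) and
:class:`BruxismResults` (estimates, diagnostics, ``summary()``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .artifacts import FilterSpec, apply_filter
from .core import EpochSet, EvalReport, FeatureMatrix, Recording, ValidationError
from .epochs import LabelingConfig, label_samples, make_epochs
from .features import HiguchiConfig, extract_features

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Which sessions train and which single session is held out."""

    train_sessions: list[str]
    test_session: str
    cv_folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.test_session in self.train_sessions:
            raise ValidationError("test_session must not be among train_sessions")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


@dataclass
class SmoteConfig:
    """Synthetic minority oversampling settings.

    ``target_ratio`` is the minority/majority count ratio after resampling
    (1.0 = fully balanced); ``k_neighbors`` the neighborhood size for
    interpolation, reduced (with a log message) when the minority class is
    smaller than requested.
    """

    k_neighbors: int = 5
    rng_seed: int = 0
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValidationError("target_ratio must be > 0")


@dataclass
class ModelConfig:
    """Boosted-ensemble settings and the CV hyperparameter grid."""

    n_estimators: int = 100
    learning_rate: float = 1.0
    base_depth: int = 1
    grid: dict[str, list] | None = field(default_factory=lambda: {"n_estimators": [50, 100, 200]})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValidationError("n_estimators must be >= 1")


def smote_oversample(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating synthetic minority rows.

    Each synthetic row is ``x + u·(x_nn − x)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the k nearest minority neighbors (Euclidean) of a
    randomly drawn minority row. Original rows are preserved verbatim and
    synthetic rows are appended after them.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValidationError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("SMOTE needs both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_target = int(round(cfg.target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValidationError("SMOTE needs at least 2 minority samples")
    k = cfg.k_neighbors
    if n_min <= k:
        k = n_min - 1
        logger.info("SMOTE: minority count %d <= k_neighbors, reducing k to %d", n_min, k)

    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)  # +1: self is its own neighbor
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.rng_seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0, 1, size=n_new)
    x_base = X_min[base]
    x_nn = X_min[neighbor_idx[base, pick]]
    X_new = x_base + u[:, None] * (x_nn - x_base)

    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


def zstandardize(
    train_X: np.ndarray, apply_X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Column-wise z-scores with parameters fitted on the training rows only.

    Constant columns (sd = 0) are mapped to 0 with a warning. Returns
    ``(train_Z, apply_Z, means, sds)``; ``apply_Z`` is None when ``apply_X``
    is None.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.size == 0:
        raise ValidationError("empty training matrix")
    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0)
    zero_sd = sds == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} constant feature column(s) mapped to 0", stacklevel=2
        )
    safe = np.where(zero_sd, 1.0, sds)
    train_Z = (train_X - means) / safe
    train_Z[:, zero_sd] = 0.0
    apply_Z = None
    if apply_X is not None:
        apply_X = np.asarray(apply_X, dtype=float)
        apply_Z = (apply_X - means) / safe
        apply_Z[:, zero_sd] = 0.0
    return train_Z, apply_Z, means, sds


def train_classifier(X: np.ndarray, y: np.ndarray, cfg: ModelConfig | None = None):
    """Fit an AdaBoost ensemble of shallow decision trees (SAMME weighting)."""
    cfg = cfg or ModelConfig()
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=cfg.base_depth, random_state=cfg.rng_seed),
        n_estimators=cfg.n_estimators,
        learning_rate=cfg.learning_rate,
        random_state=cfg.rng_seed,
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Confusion counts and precision/recall/F1/MCC; any 0/0 is 0."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    def safe_div(a: float, b: float) -> float:
        return a / b if b != 0 else 0.0

    precision = safe_div(tp, tp + fp)
    recall = safe_div(tp, tp + fn)
    f1 = safe_div(2 * precision * recall, precision + recall)
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = safe_div(tp * tn - fp * fn, denom)
    prevalence = safe_div(tp + fn, len(y_true))
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1, mcc=float(mcc),
        prevalence=prevalence,
    )


def _fit_fold(X_tr, y_tr, X_val, smote_cfg: SmoteConfig, model_cfg: ModelConfig):
    """Oversample + scale + fit on one training fold; predict the held-out rows.

    All transform parameters come from the training rows only.
    """
    X_res, y_res = smote_oversample(X_tr, y_tr, smote_cfg)
    X_res_z, X_val_z, _, _ = zstandardize(X_res, X_val)
    clf = train_classifier(X_res_z, y_res, model_cfg)
    return clf.predict(X_val_z)


def stratified_cv(
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    smote_cfg: SmoteConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> dict:
    """Stratified k-fold CV on the training pool, selecting by mean F1.

    SMOTE and z-standardization are fit inside each training fold only,
    so no oversampled or scaled information crosses the fold boundary.
    Returns per-fold metrics per grid candidate and the selected
    hyperparameters.
    """
    smote_cfg = smote_cfg or SmoteConfig()
    model_cfg = model_cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < plan.cv_folds:
        raise ValidationError(
            f"minority class count {counts.min()} < cv_folds {plan.cv_folds}"
        )
    grid = model_cfg.grid or {"n_estimators": [model_cfg.n_estimators]}
    candidates = []
    for n_est in grid.get("n_estimators", [model_cfg.n_estimators]):
        for lr in grid.get("learning_rate", [model_cfg.learning_rate]):
            candidates.append(
                ModelConfig(
                    n_estimators=n_est,
                    learning_rate=lr,
                    base_depth=model_cfg.base_depth,
                    grid=None,
                    rng_seed=model_cfg.rng_seed,
                )
            )
    skf = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.rng_seed)
    folds = list(skf.split(X, y))
    results = []
    for cand in candidates:
        fold_reports = []
        for tr_idx, val_idx in folds:
            y_pred = _fit_fold(X[tr_idx], y[tr_idx], X[val_idx], smote_cfg, cand)
            fold_reports.append(evaluate(y[val_idx], y_pred))
        results.append(
            {
                "params": {"n_estimators": cand.n_estimators, "learning_rate": cand.learning_rate},
                "fold_f1": [r.f1 for r in fold_reports],
                "mean_f1": float(np.mean([r.f1 for r in fold_reports])),
                "fold_reports": fold_reports,
            }
        )
    best = max(results, key=lambda r: r["mean_f1"])
    return {"candidates": results, "best_params": best["params"], "best_mean_f1": best["mean_f1"]}


# ----------------------------------------------------------------------------
# session-level preprocessing and feature extraction


def preprocess_epochs(
    epochs: EpochSet,
    bandpass: FilterSpec | None = None,
    notch: FilterSpec | None = None,
) -> EpochSet:
    """Per-epoch preprocessing: mean-center, band-pass, notch, per channel.

    Applying the filters to 1-s windows mimics an online detector that never
    sees future samples beyond the current epoch; zero-phase application
    keeps features aligned within the window. Filters run vectorised along
    the sample axis but are numerically identical to per-channel calls.
    """
    from scipy import signal as sps

    bandpass = bandpass or FilterSpec(kind="bandpass_iir", band_hz=(5.0, 62.0))
    notch = notch or FilterSpec(kind="notch_iir", notch_hz=50.0)
    fs = epochs.fs
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    sos = sps.butter(bandpass.order, list(bandpass.band_hz), btype="band", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=2)
    b, a = sps.iirnotch(notch.notch_hz, notch.quality, fs=fs)
    data = sps.filtfilt(b, a, data, axis=2)
    return EpochSet(
        data=data,
        labels=epochs.labels.copy(),
        fs=fs,
        activity_of_epoch=list(epochs.activity_of_epoch),
        channel_labels=list(epochs.channel_labels),
        session_id=epochs.session_id,
    )


def preprocess_recording(recording: Recording) -> Recording:
    """Whole-session alternative: filter each channel before epoching."""
    data = np.empty_like(recording.data)
    for ch in range(recording.n_channels):
        x = recording.data[ch] - recording.data[ch].mean()
        x = apply_filter(x, recording.fs, FilterSpec(kind="bandpass_iir", band_hz=(5.0, 62.0)))
        data[ch] = apply_filter(x, recording.fs, FilterSpec(kind="notch_iir", notch_hz=50.0))
    return Recording(
        data=data,
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        session_id=recording.session_id,
        open_channel=recording.open_channel,
    )


def session_features(
    recording: Recording,
    annotations,
    labeling_cfg: LabelingConfig | None = None,
    higuchi_cfg: HiguchiConfig | None = None,
    filter_mode: str = "per_epoch",
) -> FeatureMatrix:
    """Full per-session chain: label → epoch → preprocess → features."""
    labeling_cfg = labeling_cfg or LabelingConfig()
    if filter_mode not in ("per_epoch", "session"):
        raise ValidationError("filter_mode must be 'per_epoch' or 'session'")
    rec = preprocess_recording(recording) if filter_mode == "session" else recording
    sample_labels = label_samples(rec, annotations, labeling_cfg)
    eps = make_epochs(rec, sample_labels, annotations, labeling_cfg)
    if filter_mode == "per_epoch":
        eps = preprocess_epochs(eps)
    return extract_features(eps, higuchi_cfg)


# ----------------------------------------------------------------------------
# statsmodels-style model / results objects


class BruxismModel:
    """Cross-session jaw-clench detection model.

    Built from per-session feature matrices and a :class:`SplitPlan`; ``fit``
    runs the CV hyperparameter search on the pooled training sessions, then
    trains the final SMOTE + z-scored AdaBoost on all training rows and
    scores the held-out session, returning :class:`BruxismResults`.
    """

    def __init__(
        self,
        features_by_session: dict[str, FeatureMatrix],
        plan: SplitPlan,
        smote_cfg: SmoteConfig | None = None,
        model_cfg: ModelConfig | None = None,
    ):
        missing = [s for s in plan.train_sessions + [plan.test_session] if s not in features_by_session]
        if missing:
            raise ValidationError(f"sessions missing from features: {missing}")
        if len(plan.train_sessions) < 1:
            raise ValidationError("need at least one training session")
        self.plan = plan
        self.smote_cfg = smote_cfg or SmoteConfig()
        self.model_cfg = model_cfg or ModelConfig()
        self._features = features_by_session

        train = [features_by_session[s] for s in plan.train_sessions]
        self.column_names = train[0].column_names
        for fm in features_by_session.values():
            if fm.column_names != self.column_names:
                raise ValidationError("feature columns differ across sessions")
        self.X_train = np.vstack([fm.values for fm in train])
        self.y_train = np.concatenate([np.asarray(fm.labels, dtype=int) for fm in train])
        test = features_by_session[plan.test_session]
        self.X_test = test.values
        self.y_test = np.asarray(test.labels, dtype=int)

    @classmethod
    def from_study(
        cls,
        sessions,
        plan: SplitPlan,
        labeling_cfg: LabelingConfig | None = None,
        higuchi_cfg: HiguchiConfig | None = None,
        smote_cfg: SmoteConfig | None = None,
        model_cfg: ModelConfig | None = None,
        filter_mode: str = "per_epoch",
    ) -> "BruxismModel":
        """Construct from raw (Recording, annotations) pairs."""
        feats = {
            rec.session_id: session_features(rec, anns, labeling_cfg, higuchi_cfg, filter_mode)
            for rec, anns in sessions
        }
        return cls(feats, plan, smote_cfg, model_cfg)

    def fit(self, run_cv: bool = True) -> "BruxismResults":
        """Optimise, train on all training rows, score the held-out session."""
        cv_report = None
        model_cfg = self.model_cfg
        if run_cv and model_cfg.grid:
            cv_report = stratified_cv(self.X_train, self.y_train, self.plan, self.smote_cfg, model_cfg)
            best = cv_report["best_params"]
            model_cfg = ModelConfig(
                n_estimators=best["n_estimators"],
                learning_rate=best["learning_rate"],
                base_depth=model_cfg.base_depth,
                grid=None,
                rng_seed=model_cfg.rng_seed,
            )
        X_res, y_res = smote_oversample(self.X_train, self.y_train, self.smote_cfg)
        X_res_z, X_test_z, means, sds = zstandardize(X_res, self.X_test)
        clf = train_classifier(X_res_z, y_res, model_cfg)
        y_pred = clf.predict(X_test_z)
        report = evaluate(self.y_test, y_pred)
        return BruxismResults(
            model=self,
            classifier=clf,
            report=report,
            cv_report=cv_report,
            selected_config=model_cfg,
            y_pred=y_pred,
            scaler=(means, sds),
        )


class BruxismResults:
    """Fitted cross-session detector: estimates, diagnostics, summary."""

    def __init__(self, model, classifier, report, cv_report, selected_config, y_pred, scaler):
        self.model = model
        self.classifier = classifier
        self.report = report
        self.cv_report = cv_report
        self.selected_config = selected_config
        self.y_pred = y_pred
        self.scaler = scaler

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict labels for new feature rows (scaled with training params)."""
        means, sds = self.scaler
        safe = np.where(sds == 0, 1.0, sds)
        Z = (np.asarray(X, dtype=float) - means) / safe
        Z[:, sds == 0] = 0.0
        return self.classifier.predict(Z)

    def run_log(self) -> dict:
        """Every config and seed that determined this fit, JSON-serialisable."""
        return {
            "plan": {
                "train_sessions": self.model.plan.train_sessions,
                "test_session": self.model.plan.test_session,
                "cv_folds": self.model.plan.cv_folds,
                "rng_seed": self.model.plan.rng_seed,
            },
            "smote": {
                "k_neighbors": self.model.smote_cfg.k_neighbors,
                "rng_seed": self.model.smote_cfg.rng_seed,
                "target_ratio": self.model.smote_cfg.target_ratio,
            },
            "model": {
                "n_estimators": self.selected_config.n_estimators,
                "learning_rate": self.selected_config.learning_rate,
                "base_depth": self.selected_config.base_depth,
                "rng_seed": self.selected_config.rng_seed,
            },
            "cv": None
            if self.cv_report is None
            else {
                "best_params": self.cv_report["best_params"],
                "best_mean_f1": self.cv_report["best_mean_f1"],
                "candidates": [
                    {"params": c["params"], "mean_f1": c["mean_f1"], "fold_f1": c["fold_f1"]}
                    for c in self.cv_report["candidates"]
                ],
            },
            "report": self.report.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.run_log(), fh, indent=2)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Cross-session bruxism detection",
            "=" * 47,
            f"train sessions : {', '.join(self.model.plan.train_sessions)}"
            f"  (n={len(self.model.y_train)})",
            f"test session   : {self.model.plan.test_session}  (n={r.n_test})",
            f"test prevalence: {r.prevalence:.3f}",
            f"classifier     : AdaBoost, {self.selected_config.n_estimators} stumps"
            f" (depth {self.selected_config.base_depth})",
        ]
        if self.cv_report is not None:
            lines.append(
                f"CV ({self.model.plan.cv_folds}-fold)  : best mean F1 "
                f"{self.cv_report['best_mean_f1']:.3f} at {self.cv_report['best_params']}"
            )
        lines += [
            "-" * 47,
            f"confusion      : TP={r.tp}  FP={r.fp}  FN={r.fn}  TN={r.tn}",
            f"precision      : {r.precision:.3f}",
            f"recall         : {r.recall:.3f}",
            f"F1             : {r.f1:.3f}",
            f"MCC            : {r.mcc:.3f}",
            "=" * 47,
        ]
        return "\n".join(lines)


def run_pipeline(
    sessions,
    plan: SplitPlan,
    labeling_cfg: LabelingConfig | None = None,
    higuchi_cfg: HiguchiConfig | None = None,
    smote_cfg: SmoteConfig | None = None,
    model_cfg: ModelConfig | None = None,
    filter_mode: str = "per_epoch",
) -> tuple[EvalReport, dict]:
    """End-to-end: preprocess → epoch → features → CV → fit → held-out report.

    Thin functional wrapper over :class:`BruxismModel`; returns the
    evaluation report and the JSON-serialisable run log.
    """
    if len(plan.train_sessions) < 2:
        raise ValidationError("need at least 2 training sessions")
    m = BruxismModel.from_study(
        sessions, plan, labeling_cfg, higuchi_cfg, smote_cfg, model_cfg, filter_mode
    )
    res = m.fit()
    return res.report, res.run_log()
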