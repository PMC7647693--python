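"""RBF-SVM classification of lysine windows, evaluation metrics, and the
end-to-end estimator.

The classifier is a support vector machine with a radial basis function
kernel K(x, x') = exp(-r ||x - x'||^2); the LIBSVM-style cost ``c`` and
``gamma`` (r) are either fixed or chosen by exhaustive grid search
(c in 2^-5..2^15, r in 2^-15..2^3, both in steps of 2^2) maximizing the
cross-validated Matthews correlation coefficient.  MCC is the model-selection
benchmark throughout: positive and negative site counts are heavily skewed in
real succinylome data, so accuracy alone is not informative.

Evaluation metrics from the pooled confusion counts:

    Sn  = TP / (TP + FN)                      (sensitivity)
    Sp  = TN / (TN + FP)                      (specificity)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.

:class:`SuccinylationSiteClassifier` is the scikit-learn-style estimator tying
everything together: it takes raw 31-mer windows, builds the configured
feature blocks (AAC / AAPC / CKSAAP / CIKSAAP hybrids), runs mRMR + SFS when
an informative k-spaced pair subset is requested, and fits a probability-
calibrated RBF-SVM.  The fitted feature recipe travels with the model so
predictions are exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import logging

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as _feat
from .seqio import ProteinRecord, SequenceWindow, window_residues

_logger = logging.getLogger(__name__)

ARCHIVE_VERSION = 1

FEATURE_SETS = (
    "AAC", "AAPC", "CKSAAP",
    "AAC+AAPC", "AAC+CIKSAAP", "AAPC+CIKSAAP", "AAC+AAPC+CIKSAAP",
)


class ModelArchiveError(ValueError):
    """Raised when a persisted model archive is missing or malformed."""


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters in the LIBSVM convention (cost c, gamma r)."""

    c: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"cost must be > 0, got {self.c}")
        if not (self.gamma == "scale"
                or (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
            raise ValueError(f"gamma must be > 0 or 'scale', got {self.gamma}")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the four derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sn(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def sp(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def mcc(self) -> float:
        f1 = self.tp + self.fn
        f2 = self.tn + self.fp
        f3 = self.tp + self.fp
        f4 = self.tn + self.fn
        if 0 in (f1, f2, f3, f4):
            return 0.0
        num = float(self.tp) * self.tn - float(self.fn) * self.fp
        return num / math.sqrt(float(f1) * f2 * f3 * f4)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sn": self.sn, "sp": self.sp, "acc": self.acc,
                "mcc": self.mcc}


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics` from the four confusion counts."""
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve: ordered (FPR, TPR) points and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC from continuous scores.

    Scores tied at the same value move the curve in a single simultaneous
    step.  A perfect ranking gives AUC = 1, a perfectly inverted one AUC = 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(np.trapezoid(tpr, fpr)))


# ---------------------------------------------------------------------------
# SVM training and cross-validation on encoded matrices


def _make_svc(config: SvmConfig, seed: int | None) -> SVC:
    return SVC(C=config.c, gamma=config.gamma, kernel="rbf",
               random_state=seed)


def train_svm(X, y, config: SvmConfig | None = None,
              seed: int | None = 0) -> CalibratedClassifierCV:
    """Fit an RBF-SVM with Platt-style probability scores.

    The sigmoid calibrator is fit on cross-validated decision values of the
    training data; the margin classifier itself is refit on all samples
    (``ensemble=False``), so decision values and probabilities come from a
    single hyperplane.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < 2:
        raise ValueError("probability calibration needs >= 2 samples per "
                         "class")
    cal_folds = int(min(5, counts.min()))
    clf = CalibratedClassifierCV(_make_svc(config or SvmConfig(), seed),
                                 method="sigmoid", cv=cal_folds,
                                 ensemble=False)
    return clf.fit(X, y)


def decision_values(fitted: CalibratedClassifierCV, X) -> np.ndarray:
    """Signed margin distances of the calibrated model's underlying SVC."""
    return fitted.calibrated_classifiers_[0].estimator.decision_function(
        np.asarray(X, dtype=float))


@dataclass
class CvResult:
    """Pooled cross-validation outcome with per-fold trace and held-out scores."""

    pooled: ConfusionMetrics
    folds: list[ConfusionMetrics]
    scores: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def roc(self) -> RocCurve:
        return roc_auc(self.scores, self.y)


def cross_validate_matrix(X, y, config: SvmConfig | None = None,
                          folds: int = 10, seed: int = 0,
                          ) -> tuple[ConfusionMetrics, CvResult]:
    """Stratified k-fold CV of the RBF-SVM on an encoded matrix.

    Returns ``(pooled_metrics, CvResult)``: confusion counts pooled over the
    held-out folds, the per-fold trace, and the held-out decision values
    (aligned with the input order) for ROC construction.  Folds are seeded
    and stratified; remainders are spread so fold sizes differ by at most
    one sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("cross-validation needs exactly two classes")
    if counts.min() < folds:
        raise ValueError(f"smallest class has {counts.min()} samples; cannot "
                         f"stratify into {folds} folds")
    positive = classes[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    fold_metrics: list[ConfusionMetrics] = []
    tp = fp = tn = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = _make_svc(config or SvmConfig(), seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        scores[test_idx] = clf.decision_function(X[test_idx])
        truth = y[test_idx]
        f_tp = int(((pred == positive) & (truth == positive)).sum())
        f_fp = int(((pred == positive) & (truth != positive)).sum())
        f_tn = int(((pred != positive) & (truth != positive)).sum())
        f_fn = int(((pred != positive) & (truth == positive)).sum())
        fold_metrics.append(ConfusionMetrics(f_tp, f_fp, f_tn, f_fn))
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
    pooled = ConfusionMetrics(tp, fp, tn, fn)
    return pooled, CvResult(pooled, fold_metrics, scores, y.copy())


DEFAULT_C_EXPONENTS = tuple(range(-5, 16, 2))      # 2^-5 .. 2^15, 11 values
DEFAULT_GAMMA_EXPONENTS = tuple(range(-15, 4, 2))  # 2^-15 .. 2^3, 10 values


def grid_search(X, y, cv_folds: int = 10, seed: int = 0,
                c_exponents: Sequence[int] = DEFAULT_C_EXPONENTS,
                gamma_exponents: Sequence[int] = DEFAULT_GAMMA_EXPONENTS,
                ) -> SvmConfig:
    """Exhaustive (c, gamma) search maximizing cross-validated MCC.

    The default grid is the 11 x 10 LIBSVM-style lattice.  Ties go to the
    smaller cost, then the smaller gamma.
    """
    best: tuple[float, SvmConfig] | None = None
    for ce in c_exponents:
        for ge in gamma_exponents:
            config = SvmConfig(c=2.0 ** ce, gamma=2.0 ** ge)
            pooled, _ = cross_validate_matrix(X, y, config, cv_folds, seed)
            if best is None or pooled.mcc > best[0]:
                best = (pooled.mcc, config)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# feature recipe: the exact encoding pipeline a fitted model carries


@dataclass
class FeatureRecipe:
    """Everything needed to re-encode windows exactly as at training time.

    ``feature_set`` is one of :data:`FEATURE_SETS`; ``dipeptides`` holds the
    significant-dipeptide subset for an AAPC block (``None`` = all 400, an
    empty list = an empty block when nothing passed the screen);
    ``ksaap_attributes`` holds the informative k-spaced pair names for a
    CIKSAAP block.
    """

    feature_set: str
    n_flank: int = 15
    k_min: int = 1
    k_max: int = 5
    dipeptides: list[str] | None = None
    ksaap_attributes: list[str] | None = None

    def parts(self) -> list[str]:
        return self.feature_set.split("+")

    def encoders(self) -> list:
        enc = []
        for part in self.parts():
            if part == "AAC":
                enc.append(_feat.AacEncoder())
            elif part == "AAPC":
                enc.append(_feat.AapcEncoder(dipeptides=self.dipeptides))
            elif part == "CKSAAP":
                enc.append(_feat.CksaapEncoder(k_min=self.k_min,
                                               k_max=self.k_max))
            elif part == "CIKSAAP":
                if self.ksaap_attributes is None:
                    raise ValueError("CIKSAAP block requires selected "
                                     "ksaap_attributes")
                enc.append(_feat.CksaapEncoder(
                    attributes=self.ksaap_attributes,
                    k_min=self.k_min, k_max=self.k_max))
            else:
                raise ValueError(f"unknown feature block {part!r} in "
                                 f"{self.feature_set!r}")
        return enc

    def encode(self, windows: Sequence[SequenceWindow | str]) -> np.ndarray:
        return np.hstack([e.fit(windows).transform(windows)
                          for e in self.encoders()])

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for e in self.encoders():
            names.extend(e.get_feature_names_out())
        return names

    def to_dict(self) -> dict:
        return {"feature_set": self.feature_set, "n_flank": self.n_flank,
                "k_min": self.k_min, "k_max": self.k_max,
                "dipeptides": self.dipeptides,
                "ksaap_attributes": self.ksaap_attributes}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRecipe":
        return cls(**d)


def cross_validate(windows: Sequence[SequenceWindow | str], labels,
                   recipe: FeatureRecipe, config: SvmConfig | None = None,
                   folds: int = 10, seed: int = 0,
                   ) -> tuple[ConfusionMetrics, CvResult]:
    """Encode windows through ``recipe`` and cross-validate the SVM."""
    X = recipe.encode(windows)
    return cross_validate_matrix(X, labels, config=config, folds=folds,
                                 seed=seed)


# ---------------------------------------------------------------------------
# the end-to-end estimator


class SuccinylationSiteClassifier(ClassifierMixin, BaseEstimator):
    """Lysine succinylation site classifier over 31-mer sequence windows.

    A scikit-learn-style estimator: ``fit`` takes a sequence of windows
    (strings or :class:`~succpred.seqio.SequenceWindow`) and binary labels,
    builds the configured feature blocks, optionally selects informative
    k-spaced pairs (mRMR ranking + sequential forward selection, when the
    feature set contains ``CIKSAAP``) and significant dipeptides (when it
    contains ``AAPC``), then fits a probability-calibrated RBF-SVM.

    Parameters
    ----------
    feature_set :
        One of ``"AAC"``, ``"AAPC"``, ``"CKSAAP"``, ``"AAC+AAPC"``,
        ``"AAC+CIKSAAP"``, ``"AAPC+CIKSAAP"``, ``"AAC+AAPC+CIKSAAP"``.
    diff_min, alpha :
        Dipeptide screening rule: keep dipeptides with |probability
        difference| > ``diff_min`` and P < ``alpha``.
    selection_budget, selection_cv_folds :
        SFS cap (default 30 attributes) and the fold count of its inner CV.
    C, gamma :
        Fixed SVM hyperparameters; ignored when ``tune=True``, in which case
        the exhaustive (c, gamma) grid is searched with ``tune_cv_folds``
        folds.
    random_state :
        Seeds every stochastic step (fold shuffling, Platt calibration).
    """

    def __init__(self, feature_set: str = "AAC+CIKSAAP", n_flank: int = 15,
                 k_min: int = 1, k_max: int = 5,
                 diff_min: float = 0.02, alpha: float = 0.05,
                 selection_budget: int = 30, selection_cv_folds: int = 10,
                 C: float = 1.0, gamma: float | str = "scale",
                 tune: bool = False, tune_cv_folds: int = 10,
                 random_state: int | None = 0):
        self.feature_set = feature_set
        self.n_flank = n_flank
        self.k_min = k_min
        self.k_max = k_max
        self.diff_min = diff_min
        self.alpha = alpha
        self.selection_budget = selection_budget
        self.selection_cv_folds = selection_cv_folds
        self.C = C
        self.gamma = gamma
        self.tune = tune
        self.tune_cv_folds = tune_cv_folds
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        from .selection import mrmr_rank, sfs_select

        windows = list(X)
        y = np.asarray(y).ravel()
        if len(windows) != y.size:
            raise ValueError("X and y length mismatch")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}, "
                             f"got {self.feature_set!r}")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        positive = self.classes_[1]
        y_enc = (y == positive).astype(int)
        seed = self.random_state if self.random_state is not None else 0

        pos_windows = [w for w, t in zip(windows, y_enc) if t == 1]
        neg_windows = [w for w, t in zip(windows, y_enc) if t == 0]

        parts = self.feature_set.split("+")
        dipeptides = None
        if "AAPC" in parts:
            self.dipeptide_stats_ = _feat.dipeptide_diff_stats(pos_windows,
                                                               neg_windows)
            dipeptides = _feat.select_significant_dipeptides(
                self.dipeptide_stats_, self.diff_min, self.alpha)
            if not dipeptides:
                # The screening rule found nothing: the AAPC block of a
                # hybrid contributes no attributes (an empty block), exactly
                # as the screened-subset construction dictates.  A pure AAPC
                # model would be unfittable, so it alone falls back to the
                # full 400-dipeptide composition.
                if self.feature_set == "AAPC":
                    _logger.warning("no dipeptide passes the screening rule; "
                                    "AAPC model falls back to all 400 "
                                    "dipeptides")
                    dipeptides = None
                else:
                    _logger.warning("no dipeptide passes the screening rule; "
                                    "AAPC block of %s is empty",
                                    self.feature_set)
        ksaap_attributes = None
        if "CIKSAAP" in parts:
            counts, slots = _feat.ksaap_count_matrix(windows, self.k_min,
                                                     self.k_max)
            names = [a.name for a in
                     _feat.all_ksaap_attributes(self.k_min, self.k_max)]
            self.mrmr_ranking_ = mrmr_rank(counts, y_enc,
                                           top_m=self.selection_budget,
                                           feature_names=names)
            values = counts.astype(float)
            n_k = self.k_max - self.k_min + 1
            for ki in range(n_k):
                denom = slots[:, ki]
                block = slice(400 * ki, 400 * (ki + 1))
                np.divide(values[:, block], denom[:, None],
                          out=values[:, block], where=denom[:, None] > 0)
            self.sfs_result_ = sfs_select(
                self.mrmr_ranking_, values, y_enc,
                budget=self.selection_budget,
                cv_folds=self.selection_cv_folds, seed=seed,
                svm_config=SvmConfig(c=self.C, gamma=self.gamma))
            ksaap_attributes = list(self.sfs_result_.selected)

        self.recipe_ = FeatureRecipe(
            feature_set=self.feature_set, n_flank=self.n_flank,
            k_min=self.k_min, k_max=self.k_max, dipeptides=dipeptides,
            ksaap_attributes=ksaap_attributes)
        X_mat = self.recipe_.encode(windows)
        if self.tune:
            self.config_ = grid_search(X_mat, y_enc,
                                       cv_folds=self.tune_cv_folds, seed=seed)
        else:
            self.config_ = SvmConfig(c=self.C, gamma=self.gamma)
        self.svm_ = train_svm(X_mat, y_enc, self.config_, seed)
        self.n_features_in_ = X_mat.shape[1]
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "svm_"):
            raise ValueError("classifier is not fitted")

    def _encode(self, X) -> np.ndarray:
        self._check_fitted()
        return self.recipe_.encode(list(X))

    def decision_function(self, X) -> np.ndarray:
        return decision_values(self.svm_, self._encode(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.svm_.predict_proba(self._encode(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= threshold, self.classes_[1],
                        self.classes_[0])

    def cross_validate(self, X, y, folds: int = 10
                       ) -> tuple[ConfusionMetrics, CvResult]:
        """CV of the fitted recipe + config on new (or training) windows."""
        self._check_fitted()
        positive = self.classes_[1]
        y_enc = (np.asarray(y).ravel() == positive).astype(int)
        seed = self.random_state if self.random_state is not None else 0
        return cross_validate(list(X), y_enc, self.recipe_, self.config_,
                              folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# whole-protein scanning and evaluation


@dataclass(frozen=True)
class SitePrediction:
    """One scored candidate lysine: provenance, window, probability, call."""

    protein_id: str
    position: int
    window: str
    score: float
    call: bool


def predict_sites(model: SuccinylationSiteClassifier,
                  proteins: Sequence[ProteinRecord],
                  threshold: float = 0.5) -> list[SitePrediction]:
    """Score every lysine in every protein; call = score >= threshold.

    Output is sorted by protein id then position.  Proteins without lysines
    simply contribute no rows.
    """
    model._check_fitted()
    n = model.recipe_.n_flank
    keys: list[tuple[str, int]] = []
    windows: list[str] = []
    for prot in proteins:
        for i, ch in enumerate(prot.sequence):
            if ch == "K":
                keys.append((prot.id, i + 1))
                windows.append(window_residues(prot.sequence, i + 1, n))
    if not windows:
        return []
    scores = model.predict_proba(windows)[:, 1]
    preds = [SitePrediction(pid, pos, w, float(s), bool(s >= threshold))
             for (pid, pos), w, s in zip(keys, windows, scores)]
    return sorted(preds, key=lambda p: (p.protein_id, p.position))


def write_predictions(predictions: Iterable[SitePrediction],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\twindow\tscore\tcall\n")
        for p in predictions:
            fh.write(f"{p.protein_id}\t{p.position}\t{p.window}\t"
                     f"{p.score:.6f}\t{int(p.call)}\n")


def read_predictions(path: str | Path) -> list[SitePrediction]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [SitePrediction(r.protein_id, int(r.position), str(r.window),
                           float(r.score), bool(int(r.call)))
            for r in df.itertuples(index=False)]


def evaluate_predictions(predictions: Sequence[SitePrediction],
                         annotations) -> ConfusionMetrics:
    """Confusion metrics of calls against annotated lysines.

    Every annotated (protein, position) must have a prediction; disjoint key
    spaces are an error (wrong file pairing).
    """
    from .seqio import POSITIVE

    pred_by_key = {(p.protein_id, p.position): p for p in predictions}
    missing = [(a.protein_id, a.position) for a in annotations
               if (a.protein_id, a.position) not in pred_by_key]
    if len(missing) == len(list(annotations)) or not annotations:
        raise ValueError("predictions and annotations share no "
                         "(protein, position) keys")
    if missing:
        raise KeyError(f"{len(missing)} annotated sites lack predictions, "
                       f"e.g. {missing[:3]}")
    tp = fp = tn = fn = 0
    for a in annotations:
        call = pred_by_key[(a.protein_id, a.position)].call
        if a.label == POSITIVE:
            tp, fn = tp + call, fn + (not call)
        else:
            fp, tn = fp + call, tn + (not call)
    return ConfusionMetrics(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# persistence: solver state + JSON sidecar


def save_model(model: SuccinylationSiteClassifier, path: str | Path) -> None:
    """Persist a fitted model as a directory archive.

    ``svm.joblib`` holds the solver state; ``model.json`` holds the feature
    recipe, hyperparameters, class labels, and seed — everything needed to
    reproduce predictions.
    """
    model._check_fitted()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.svm_, path / "svm.joblib")
    sidecar = {
        "archive_version": ARCHIVE_VERSION,
        "recipe": model.recipe_.to_dict(),
        "config": {"c": model.config_.c, "gamma": model.config_.gamma},
        "classes": [_json_safe(c) for c in model.classes_],
        "params": model.get_params(),
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def _json_safe(v):
    return v.item() if isinstance(v, np.generic) else v


def load_model(path: str | Path) -> SuccinylationSiteClassifier:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    sidecar_path = path / "model.json"
    svm_path = path / "svm.joblib"
    if not sidecar_path.exists() or not svm_path.exists():
        raise ModelArchiveError(f"{path}: not a model archive (expected "
                                "model.json and svm.joblib)")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("archive_version") != ARCHIVE_VERSION:
            raise ModelArchiveError(
                f"{path}: unsupported archive version "
                f"{sidecar.get('archive_version')!r}")
        model = SuccinylationSiteClassifier(**sidecar["params"])
        model.recipe_ = FeatureRecipe.from_dict(sidecar["recipe"])
        model.config_ = SvmConfig(**sidecar["config"])
        model.classes_ = np.asarray(sidecar["classes"])
        model.svm_ = joblib.load(svm_path)
    except ModelArchiveError:
        raise
    except Exception as exc:  # malformed JSON / joblib payload
        raise ModelArchiveError(f"{path}: malformed model archive: {exc}") \
            from exc
    return model
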