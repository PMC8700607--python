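"""PLS-DA classification of tea varieties versus chicory.

Workflows: a global multi-class model over all six classes and paired
two-class models (each tea variety versus chicory) validated with a
stratified 70/30 calibration/prediction split.  PLS-DA regresses a
one-hot class matrix on the fingerprints; assignment is by argmax of
the predicted class responses for multi-class models, and by a 0.5
threshold on the adulterant-class response for paired models, with ties
going to the tea class so adulterant calls stay conservative.

The latent-variable count is cross-validated on the misassignment rate
(venetian blinds) rather than RMSECV, matching how classification
models are reported in this field.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .chemometrics import NipalsPls, select_lv, venetian_blind_splits
from .containers import FingerprintMatrix, GeneratedDataset
from .preprocess import PreprocessConfig, preprocess_matrix

TEA_CLASSES = ("black", "green", "oolong", "red", "white")


@dataclass
class ClassificationReport:
    set_name: str  # "calibration" or "prediction"
    rate_pct: float
    confusion: pd.DataFrame
    n_lv: int = 0


def classification_rate(truth, assigned) -> float:
    """Percent correctly assigned, reported to two decimals."""
    truth = np.asarray(truth)
    assigned = np.asarray(assigned)
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.shape != assigned.shape:
        raise ValueError("label vectors differ in length")
    return round(100.0 * float(np.mean(truth == assigned)), 2)


def confusion_matrix(truth, assigned, labels) -> pd.DataFrame:
    truth = np.asarray(truth)
    assigned = np.asarray(assigned)
    out = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for t, a in zip(truth, assigned):
        out.loc[t, a] += 1
    return out


def split_calibration_prediction(labels, frac_cal: float = 0.7, seed: int = 0):
    """Stratified random split: per class, ceil(frac_cal * n) rows go to
    calibration, the rest to prediction."""
    labels = np.asarray(labels)
    rng = np.random.default_rng([seed, 707])
    cal, pred = [], []
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than two members")
        perm = rng.permutation(idx)
        n_cal = int(np.ceil(frac_cal * idx.size))
        cal.extend(perm[:n_cal])
        pred.extend(perm[n_cal:])
    return np.sort(np.asarray(cal)), np.sort(np.asarray(pred))


def one_hot(labels, classes) -> np.ndarray:
    labels = np.asarray(labels)
    Y = np.zeros((labels.size, len(classes)))
    for j, cls in enumerate(classes):
        Y[labels == cls, j] = 1.0
    return Y


class PlsDaClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: NIPALS PLS on a one-hot class matrix.

    ``max_lv`` candidate latent variables are screened by venetian-blind
    cross-validation of the misassignment rate; the first-important-
    minimum rule picks ``n_components_``.  For exactly two classes with
    chicory present, assignment uses the 0.5 threshold on the chicory
    response (ties to the tea class); otherwise argmax.
    """

    def __init__(self, max_lv: int = 10, cv_splits: int = 10, rel_tol: float = 0.02):
        self.max_lv = max_lv
        self.cv_splits = cv_splits
        self.rel_tol = rel_tol

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        self.classes_ = np.array(sorted(pd.unique(labels)))
        if self.classes_.size < 2:
            raise ValueError("PLS-DA needs at least two classes")
        Y = one_hot(labels, self.classes_)
        n = X.shape[0]
        max_lv = min(self.max_lv, min(X.shape) - 1) or 1
        n_splits = min(self.cv_splits, n)
        misrate = np.zeros(max_lv)
        for train, test in venetian_blind_splits(n, n_splits):
            for a in range(1, max_lv + 1):
                model = NipalsPls(n_components=min(a, min(train.size, X.shape[1])))
                model.fit(X[train], Y[train])
                assigned = self._assign(model.predict(X[test]))
                misrate[a - 1] += float(np.sum(assigned != labels[test]))
        misrate /= n
        self.cv_misassignment_ = misrate
        self.n_components_ = select_lv(misrate, self.rel_tol)
        self.pls_ = NipalsPls(n_components=self.n_components_).fit(X, Y)
        return self

    def _assign(self, responses: np.ndarray) -> np.ndarray:
        responses = np.atleast_2d(responses)
        if self.classes_.size == 2 and "chicory" in self.classes_:
            j = int(np.flatnonzero(self.classes_ == "chicory")[0])
            tea = self.classes_[1 - j]
            return np.where(responses[:, j] > 0.5, "chicory", tea)
        return self.classes_[np.argmax(responses, axis=1)]

    def predict(self, X):
        return self._assign(self.pls_.predict(X))

    def decision_scores(self, X):
        """Predicted class responses (one column per class)."""
        return self.pls_.predict(X)


def plsda_fit(X_cal, labels_cal, max_lv: int = 10, n_splits: int = 10) -> PlsDaClassifier:
    return PlsDaClassifier(max_lv=max_lv, cv_splits=n_splits).fit(X_cal, labels_cal)


def plsda_assign(model: PlsDaClassifier, X_new) -> np.ndarray:
    return model.predict(X_new)


def _report(model, X, labels, set_name) -> ClassificationReport:
    assigned = model.predict(X)
    return ClassificationReport(
        set_name=set_name,
        rate_pct=classification_rate(labels, assigned),
        confusion=confusion_matrix(labels, assigned, model.classes_),
        n_lv=model.n_components_,
    )


def preprocess_for_classification(
    dataset: GeneratedDataset,
    channel: str,
    config: PreprocessConfig | None = None,
) -> FingerprintMatrix:
    """Full pretreatment (with QC-division correction) of one channel,
    then restriction to the sample rows."""
    matrix = dataset.channel(channel)
    processed = preprocess_matrix(
        matrix, config, qc_division=True, sequence=dataset.sequence
    )
    return processed.samples_only()


def paired_plsda_study(
    dataset: GeneratedDataset,
    tea_class: str,
    seed: int = 0,
    channel: str = "uv",
    *,
    preprocessed: FingerprintMatrix | None = None,
    max_lv: int = 10,
    n_splits: int = 10,
):
    """One paired tea-versus-chicory PLS-DA study.

    Subsets the preprocessed dataset to {tea_class, chicory}, makes the
    stratified 70/30 split, fits, and reports calibration and
    prediction classification rates.  Pass ``preprocessed`` to reuse
    one pretreatment run across the five paired studies.
    """
    if tea_class not in TEA_CLASSES:
        raise ValueError(f"tea_class must be one of {TEA_CLASSES}")
    samples = (
        preprocessed
        if preprocessed is not None
        else preprocess_for_classification(dataset, channel)
    )
    labels_all = samples.meta["class_label"].to_numpy()
    for cls in (tea_class, "chicory"):
        if cls not in labels_all:
            raise ValueError(f"class {cls!r} missing from dataset")
    mask = np.isin(labels_all, [tea_class, "chicory"])
    sub = samples.rows(mask)
    labels = sub.meta["class_label"].to_numpy()
    cal_idx, pred_idx = split_calibration_prediction(labels, 0.7, seed)
    model = PlsDaClassifier(max_lv=max_lv, cv_splits=n_splits).fit(
        sub.X[cal_idx], labels[cal_idx]
    )
    return (
        _report(model, sub.X[cal_idx], labels[cal_idx], "calibration"),
        _report(model, sub.X[pred_idx], labels[pred_idx], "prediction"),
    )


def global_plsda_study(
    dataset: GeneratedDataset,
    seed: int = 0,
    channel: str = "uv",
    *,
    preprocessed: FingerprintMatrix | None = None,
    max_lv: int = 10,
    n_splits: int = 10,
):
    """Global six-class PLS-DA model with the same 70/30 validation."""
    samples = (
        preprocessed
        if preprocessed is not None
        else preprocess_for_classification(dataset, channel)
    )
    labels = samples.meta["class_label"].to_numpy()
    cal_idx, pred_idx = split_calibration_prediction(labels, 0.7, seed)
    model = PlsDaClassifier(max_lv=max_lv, cv_splits=n_splits).fit(
        samples.X[cal_idx], labels[cal_idx]
    )
    return (
        model,
        _report(model, samples.X[cal_idx], labels[cal_idx], "calibration"),
        _report(model, samples.X[pred_idx], labels[pred_idx], "prediction"),
    )
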