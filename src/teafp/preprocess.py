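"""Fingerprint pretreatment chain.

Fixed stage order: smoothing -> baseline correction -> alignment ->
(optional) QC-division drift correction -> autoscaling.  Each stage is
exposed both as a scikit-learn-style transformer and as a plain
function; `preprocess_matrix` chains them on a FingerprintMatrix.

The QC-division correction divides every injection's trace point-wise
by the trace of the QC nearest in the injection sequence (each QC by
itself, so corrected QC fingerprints are exactly all-ones).  A small
floor epsilon, proportional to the QC trace maximum, keeps the division
stable where chromatogram baselines approach zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FingerprintMatrix, SequenceDesign


@dataclass
class PreprocessConfig:
    smooth_window: int = 11
    smooth_polyorder: int = 3
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    align_segments: int = 10
    align_max_shift: int = 20
    qc_epsilon_frac: float = 0.001

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        if self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smooth_polyorder must be < smooth_window")
        if not (0.0 < self.baseline_p < 1.0):
            raise ValueError("baseline_p must lie in (0, 1)")
        if self.align_max_shift < 0:
            raise ValueError("align_max_shift must be non-negative")


# ---------------------------------------------------------------------------
# smoothing


def smooth(trace: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay local-polynomial smoothing; length is preserved."""
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > trace.size:
        raise ValueError("smoothing window exceeds trace length")
    return savgol_filter(trace, window, polyorder)


class SavGolSmoother(TransformerMixin, BaseEstimator):
    """Row-wise Savitzky-Golay smoothing of a fingerprint matrix."""

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.apply_along_axis(smooth, -1, X, self.window, self.polyorder)


# ---------------------------------------------------------------------------
# baseline


def asls_baseline(
    trace: np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    niter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother
    with asymmetric weights: points above the baseline get weight p,
    points below 1-p), solved per iteration as a symmetric pentadiagonal
    banded system.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 10:
        raise ValueError("trace too short for baseline estimation")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    n = y.size
    # diagonals of D2'D2 (second-difference penalty), upper banded form
    d_main = np.array([1.0, 5.0] + [6.0] * (n - 4) + [5.0, 1.0])
    d_sup1 = np.array([-2.0] + [-4.0] * (n - 3) + [-2.0])
    d_sup2 = np.full(n - 2, 1.0)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = np.zeros((3, n))
        ab[0, 2:] = lam * d_sup2
        ab[1, 1:] = lam * d_sup1
        ab[2, :] = lam * d_main + w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(
    trace: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (corrected, baseline); corrected + baseline == input."""
    cfg = config or PreprocessConfig()
    baseline = asls_baseline(
        trace, cfg.baseline_lambda, cfg.baseline_p, cfg.baseline_niter
    )
    return np.asarray(trace, dtype=float) - baseline, baseline


class AslsBaseline(TransformerMixin, BaseEstimator):
    """Row-wise asymmetric-least-squares baseline removal."""

    def __init__(self, lam: float = 1e5, p: float = 0.01, niter: int = 10):
        self.lam = lam
        self.p = p
        self.niter = niter

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = X[i] - asls_baseline(X[i], self.lam, self.p, self.niter)
        return out


# ---------------------------------------------------------------------------
# alignment


def _best_lag(ref_seg: np.ndarray, seg: np.ndarray, max_shift: int) -> int:
    """Integer shift applied to ``seg`` maximizing correlation with
    ``ref_seg``, searched exhaustively over |lag| <= max_shift.

    Candidates are visited in order of increasing |lag| and a strictly
    better score is required to move on, so featureless (flat or pure
    noise) segments stay unshifted instead of drifting to an arbitrary
    lag on ties.  The score zero-fills the points a shift exposes
    (boundary-filling them would reward shifts that duplicate a large
    edge value); the output segment is still boundary-filled.
    """
    best_lag, best_score = 0, -np.inf
    for k in range(max_shift + 1):
        for lag in ((k,) if k == 0 else (-k, k)):
            shifted = _shift_segment(seg, lag)
            if lag > 0:
                shifted[:lag] = 0.0
            elif lag < 0:
                shifted[lag:] = 0.0
            score = float(np.dot(shifted, ref_seg))
            if score > best_score + 1e-12:
                best_score = score
                best_lag = lag
    return best_lag


def _shift_segment(seg: np.ndarray, lag: int) -> np.ndarray:
    """Shift right by ``lag`` points (left for negative), edge-filled."""
    if lag == 0:
        return seg.copy()
    out = np.empty_like(seg)
    if lag > 0:
        out[lag:] = seg[:-lag]
        out[:lag] = seg[0]
    else:
        out[:lag] = seg[-lag:]
        out[lag:] = seg[-1]
    return out


def align_trace(
    trace: np.ndarray,
    reference: np.ndarray,
    n_segments: int = 10,
    max_shift: int = 20,
) -> tuple[np.ndarray, list[int]]:
    """Segment-wise integer-lag alignment of one trace to a reference."""
    trace = np.asarray(trace, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trace.shape != reference.shape:
        raise ValueError("trace and reference lengths differ")
    if not np.any(reference):
        raise ValueError("reference trace is all zeros")
    bounds = np.linspace(0, trace.size, n_segments + 1).astype(int)
    out = np.empty_like(trace)
    lags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if max_shift >= b - a:
            raise ValueError("align_max_shift must be smaller than segment length")
        lag = _best_lag(reference[a:b], trace[a:b], max_shift)
        out[a:b] = _shift_segment(trace[a:b], lag)
        lags.append(lag)
    return out, lags


class SegmentAligner(TransformerMixin, BaseEstimator):
    """Align every row to a reference trace, segment by segment.

    The reference defaults to the column mean of the fitted matrix; in
    the pipeline the mean QC trace is passed explicitly.
    """

    def __init__(self, n_segments: int = 10, max_shift: int = 20, reference=None):
        self.n_segments = n_segments
        self.max_shift = max_shift
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.reference_ = (
            np.asarray(self.reference, dtype=float)
            if self.reference is not None
            else X.mean(axis=0)
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        shifts = []
        for i in range(X.shape[0]):
            out[i], lags = align_trace(
                X[i], self.reference_, self.n_segments, self.max_shift
            )
            shifts.append(lags)
        self.shifts_ = np.asarray(shifts)
        return out


def align(
    matrix: FingerprintMatrix,
    reference: np.ndarray,
    config: PreprocessConfig | None = None,
) -> FingerprintMatrix:
    cfg = config or PreprocessConfig()
    aligner = SegmentAligner(cfg.align_segments, cfg.align_max_shift, reference)
    X = aligner.fit(matrix.X).transform(matrix.X)
    return FingerprintMatrix(matrix.time, X, matrix.meta.copy(), matrix.channel)


# ---------------------------------------------------------------------------
# QC-division drift correction


def qc_correct(
    matrix: FingerprintMatrix,
    sequence: SequenceDesign | None = None,
    epsilon_frac: float = 0.001,
) -> FingerprintMatrix:
    """Divide each trace point-wise by its nearest-in-sequence QC trace.

    Ties between two QCs go to the preceding one.  Division is
    ``(x + eps) / (q + eps)`` with ``eps = epsilon_frac * max(q)``, so
    every QC row becomes exactly all-ones and a sensitivity factor
    shared by sample and QC cancels exactly.
    """
    meta = matrix.meta
    if sequence is None:
        sequence = SequenceDesign(meta[["injection_index", "sample_id", "role"]])
    qc_inj = sequence.qc_indices
    if qc_inj.size == 0:
        raise ValueError("sequence contains no QC injections")
    inj_to_row = {
        int(i): r for r, i in enumerate(meta["injection_index"].to_numpy())
    }
    X = np.empty_like(matrix.X)
    for row, inj in enumerate(meta["injection_index"].to_numpy()):
        q_inj = sequence.nearest_qc(int(inj))
        q = matrix.X[inj_to_row[q_inj]]
        eps = epsilon_frac * float(np.max(q)) if epsilon_frac > 0 else 0.0
        X[row] = (matrix.X[row] + eps) / (q + eps)
    return FingerprintMatrix(matrix.time, X, meta.copy(), matrix.channel)


# ---------------------------------------------------------------------------
# autoscaling


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and unit-variance scale each column.

    Columns with sample s.d. below 1e-12 are set to all-zeros.  Returns
    (scaled, column_means, column_sds) so prediction rows can be scaled
    with the training moments only.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least two rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = sds < 1e-12
    safe = np.where(degenerate, 1.0, sds)
    scaled = (X - means) / safe
    scaled[:, degenerate] = 0.0
    return scaled, means, sds


def apply_autoscale(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Scale new rows with stored training moments (no leakage)."""
    X = np.asarray(X, dtype=float)
    degenerate = sds < 1e-12
    safe = np.where(degenerate, 1.0, sds)
    out = (X - means) / safe
    out[:, degenerate] = 0.0
    return out


class Autoscaler(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        _, self.means_, self.sds_ = autoscale(X)
        return self

    def transform(self, X):
        return apply_autoscale(X, self.means_, self.sds_)


# ---------------------------------------------------------------------------
# pipeline


def preprocess_matrix(
    matrix: FingerprintMatrix,
    config: PreprocessConfig | None = None,
    *,
    reference: np.ndarray | None = None,
    qc_division: bool = False,
    sequence: SequenceDesign | None = None,
    autoscale_last: bool = False,
    log: list | None = None,
) -> FingerprintMatrix:
    """Run the fixed pretreatment chain on a fingerprint matrix.

    smooth -> baseline -> align -> (qc_correct if qc_division) ->
    (autoscale if autoscale_last).  The alignment reference defaults to
    the mean QC trace when QCs are present, else the mean trace.  The
    PLS estimators autoscale internally with stored training moments, so
    workflows normally leave ``autoscale_last`` off.
    """
    cfg = config or PreprocessConfig()
    X = SavGolSmoother(cfg.smooth_window, cfg.smooth_polyorder).fit(matrix.X).transform(
        matrix.X
    )
    _stage_log(log, "smooth", cfg, X)
    X = AslsBaseline(cfg.baseline_lambda, cfg.baseline_p, cfg.baseline_niter).transform(X)
    _stage_log(log, "baseline", cfg, X)
    if reference is None:
        is_qc = (matrix.meta["role"] == "qc").to_numpy()
        reference = X[is_qc].mean(axis=0) if is_qc.any() else X.mean(axis=0)
    aligner = SegmentAligner(cfg.align_segments, cfg.align_max_shift, reference)
    X = aligner.fit(X).transform(X)
    _stage_log(log, "align", cfg, X)
    out = FingerprintMatrix(matrix.time, X, matrix.meta.copy(), matrix.channel)
    if qc_division:
        out = qc_correct(out, sequence, cfg.qc_epsilon_frac)
        _stage_log(log, "qc_correct", cfg, out.X)
    if autoscale_last:
        scaled, _, _ = autoscale(out.X)
        out = FingerprintMatrix(out.time, scaled, out.meta.copy(), out.channel)
        _stage_log(log, "autoscale", cfg, out.X)
    return out


def _stage_log(log, stage, cfg, X):
    if log is not None:
        log.append(
            {
                "stage": stage,
                "params": {k: v for k, v in vars(cfg).items()},
                "checksum": float(np.sum(X)),
            }
        )
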