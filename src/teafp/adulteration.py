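"""PLS quantitation of chicory adulteration in tea extracts.

Each study mirrors the mixture design of the emulated experiment: a
six-level calibration set (0/20/40/60/80/100 % chicory) and a
five-level external validation set (15/25/50/75/85 %), five replicates
per level, built from one tea extract and one chicory extract; plus a
prediction set at 15/50/85 % built from *different* extracts of the
same classes.  Errors are root-mean-square errors in percentage points
of adulterant (RMSE in y-units, the convention of chemometric
calibration software; prediction errors can therefore exceed 100).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import NipalsPls, cross_validate_pls
from .containers import Chromatogram, GeneratedDataset
from .preprocess import AslsBaseline, PreprocessConfig, SavGolSmoother, SegmentAligner
from .synthetic import _gaussian_sum, _lot_factors, mix_fingerprints

_TAG_STUDY = 106


@dataclass
class MixtureDesign:
    """Adulteration levels (percent chicory) and replicate counts."""

    calibration_pcts: tuple = (0, 20, 40, 60, 80, 100)
    validation_pcts: tuple = (15, 25, 50, 75, 85)
    prediction_pcts: tuple = (15, 50, 85)
    replicates: int = 5

    def __post_init__(self) -> None:
        for levels in (self.calibration_pcts, self.validation_pcts, self.prediction_pcts):
            if any(not (0 <= p <= 100) for p in levels):
                raise ValueError("adulteration levels must lie in [0, 100]")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


@dataclass
class AdulterationReport:
    """One row of the study summary (per tea class and channel)."""

    tea_class: str
    channel: str
    n_lv: int
    r2: float
    rmsec: float
    rmsecv: float
    rmsev_external: float
    rmsep_prediction: float

    def as_row(self) -> dict:
        return {
            "tea_class": self.tea_class,
            "channel": self.channel,
            "LVs": self.n_lv,
            "R2": self.r2,
            "calibration_error": self.rmsec,
            "cross_validation_error": self.rmsecv,
            "external_validation_error": self.rmsev_external,
            "prediction_error": self.rmsep_prediction,
        }


def rmse_percent(y_true, y_pred) -> float:
    """Root-mean-square error in percentage points of adulterant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_fitted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_fitted = np.asarray(y_fitted, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("y_true has zero variance")
    ss_res = float(np.sum((y_true - y_fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _mixture_block(tea, chicory, levels, replicates, noise_sd, seed, key_offset):
    rows, y = [], []
    key = key_offset
    for pct in levels:
        for _ in range(replicates):
            mixed = mix_fingerprints(
                tea, chicory, pct, noise_sd=noise_sd, seed=seed, noise_key=key
            )
            rows.append(mixed.intensity)
            y.append(float(pct))
            key += 1
    return np.asarray(rows), np.asarray(y)


def build_mixture_sets(
    tea_extract: Chromatogram,
    chicory_extract: Chromatogram,
    design: MixtureDesign | None = None,
    seed: int = 0,
    *,
    noise_sd: float | None = None,
    noise_frac: float = 0.005,
):
    """Calibration and external-validation mixture matrices.

    Replicates at each level differ by fresh white-noise realizations;
    the noise s.d. defaults to ``noise_frac`` of the tea extract's
    maximum intensity (the generator's default noise level).
    """
    design = design or MixtureDesign()
    if noise_sd is None:
        noise_sd = noise_frac * float(np.max(tea_extract.intensity))
    cal_X, y_cal = _mixture_block(
        tea_extract, chicory_extract, design.calibration_pcts, design.replicates,
        noise_sd, seed, 0,
    )
    val_X, y_val = _mixture_block(
        tea_extract, chicory_extract, design.validation_pcts, design.replicates,
        noise_sd, seed, 1000,
    )
    return cal_X, val_X, y_cal, y_val


def build_prediction_set(
    other_tea_extract: Chromatogram,
    other_chicory_extract: Chromatogram,
    design: MixtureDesign | None = None,
    seed: int = 0,
    *,
    calibration_labels: tuple = (),
    noise_sd: float | None = None,
    noise_frac: float = 0.005,
):
    """Prediction mixtures from extracts unseen during calibration."""
    design = design or MixtureDesign()
    for chrom in (other_tea_extract, other_chicory_extract):
        if chrom.label and chrom.label in calibration_labels:
            raise ValueError(
                f"prediction extract {chrom.label!r} was used for calibration"
            )
    if noise_sd is None:
        noise_sd = noise_frac * float(np.max(other_tea_extract.intensity))
    pred_X, y_pred = _mixture_block(
        other_tea_extract, other_chicory_extract, design.prediction_pcts,
        design.replicates, noise_sd, seed, 2000,
    )
    return pred_X, y_pred


def _fresh_extract(dataset: GeneratedDataset, subtype: str, channel: str, seed: int, lot_key: int) -> Chromatogram:
    """Fresh lot of a class template: the ideal (drift/noise-free)
    fingerprint of a new commercial lot, with new amplitude factors."""
    tpl = dataset.templates[subtype]
    grid = dataset.uv.time
    rng = np.random.default_rng([seed, _TAG_STUDY, lot_key])
    lot = _lot_factors(tpl, rng)
    trace = _gaussian_sum(grid, tpl.peaks, channel, lot)
    return Chromatogram(grid, trace, channel, label=f"{subtype}_lot{lot_key}")


def _study_subtypes(dataset: GeneratedDataset, tea_class: str) -> tuple[str, str]:
    """Sub-templates for the calibration and prediction tea extracts.

    White tea has two sub-types; calibration draws from the first and
    prediction from the second, so the prediction extracts genuinely
    differ in composition, not just in lot.  Other classes have a
    single template and differ by lot only.
    """
    subs = sorted(
        {
            row.subtype
            for row in dataset.truth.itertuples()
            if row.class_label == tea_class
        }
    )
    if not subs:
        subs = [tea_class] if tea_class in dataset.templates else []
    if not subs:
        raise ValueError(f"no template for class {tea_class!r}")
    return subs[0], subs[-1]


def _preprocess_block(X, config: PreprocessConfig, reference=None):
    cfg = config
    Xs = SavGolSmoother(cfg.smooth_window, cfg.smooth_polyorder).transform(X)
    Xb = AslsBaseline(cfg.baseline_lambda, cfg.baseline_p, cfg.baseline_niter).transform(Xs)
    if reference is None:
        reference = Xb.mean(axis=0)
    aligner = SegmentAligner(cfg.align_segments, cfg.align_max_shift, reference)
    return aligner.fit(Xb).transform(Xb), reference


def run_adulteration_study(
    dataset: GeneratedDataset,
    tea_class: str,
    channel: str = "uv",
    config: PreprocessConfig | None = None,
    seed: int = 0,
    *,
    design: MixtureDesign | None = None,
    max_lv: int = 8,
    n_splits: int = 10,
) -> AdulterationReport:
    """One full adulteration study for a tea class and channel.

    Builds the mixture sets from a fresh calibration tea/chicory lot
    pair, preprocesses (smoothing, baseline, alignment; no QC division
    since the standalone design contains no QCs), cross-validates the
    LV count by venetian blinds, fits PLS on percent adulterant, and
    reports calibration, cross-validation, external-validation and
    prediction RMSEs plus training linearity.
    """
    counts = dataset.truth["class_label"].value_counts()
    for cls in (tea_class, "chicory"):
        if counts.get(cls, 0) < 2:
            raise ValueError(f"dataset needs at least two {cls!r} extracts")
    config = config or PreprocessConfig()
    design = design or MixtureDesign()
    cal_sub, pred_sub = _study_subtypes(dataset, tea_class)

    tea_cal = _fresh_extract(dataset, cal_sub, channel, seed, 1)
    chic_cal = _fresh_extract(dataset, "chicory", channel, seed, 2)
    tea_pred = _fresh_extract(dataset, pred_sub, channel, seed, 3)
    chic_pred = _fresh_extract(dataset, "chicory", channel, seed, 4)

    noise_frac = getattr(dataset.config, "noise_frac", 0.005)
    cal_X, val_X, y_cal, y_val = build_mixture_sets(
        tea_cal, chic_cal, design, seed, noise_frac=noise_frac
    )
    pred_X, y_pred = build_prediction_set(
        tea_pred, chic_pred, design, seed,
        calibration_labels=(tea_cal.label, chic_cal.label),
        noise_frac=noise_frac,
    )

    cal_P, reference = _preprocess_block(cal_X, config)
    val_P, _ = _preprocess_block(val_X, config, reference)
    pred_P, _ = _preprocess_block(pred_X, config, reference)

    cv = cross_validate_pls(cal_P, y_cal, max_lv=max_lv, n_splits=n_splits)
    model = NipalsPls(n_components=cv.chosen_lv).fit(cal_P, y_cal)
    fitted = model.predict(cal_P)
    return AdulterationReport(
        tea_class=tea_class,
        channel=channel,
        n_lv=model.n_components_,
        r2=r_squared(y_cal, fitted),
        rmsec=rmse_percent(y_cal, fitted),
        rmsecv=float(cv.rmsecv_by_lv[cv.chosen_lv - 1]),
        rmsev_external=rmse_percent(y_val, model.predict(val_P)),
        rmsep_prediction=rmse_percent(y_pred, model.predict(pred_P)),
    )


def run_all_studies(
    dataset: GeneratedDataset,
    channels=("uv", "fld"),
    tea_classes=("black", "green", "oolong", "red", "white"),
    config: PreprocessConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """All tea-class x channel studies as a summary table."""
    rows = [
        run_adulteration_study(dataset, tea, ch, config, seed, **kwargs).as_row()
        for ch in channels
        for tea in tea_classes
    ]
    return pd.DataFrame(rows)
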