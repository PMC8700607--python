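"""Seeded synthetic chromatogram generator.

Emulates a two-detector (UV 280 nm / FLD 280-350 nm) HPLC fingerprinting
study of five tea varieties (black, green, oolong, red, white) and
chicory root, the classic low-cost tea adulterant.  The generator encodes
the qualitative structure such a study exhibits:

* every tea shares an intense marker peak near 11 min;
* chicory gives a peak-richer UV fingerprint whose intensities are about
  100-fold lower than any tea's;
* white tea gives the most intense UV profiles, black and green the most
  intense FLD profiles, red and chicory the most FLD peaks;
* white tea splits into two sub-types, one drawn toward the chicory
  pattern;
* detector sensitivity drifts over the injection sequence (lamp ageing),
  which disperses the pooled-QC injections until corrected;
* a pooled QC plus an instrumental blank are injected at the sequence
  start and after every ten sample injections.

Everything stochastic flows from one integer seed through keyed
``numpy.random.Generator`` streams, so identical (config, seed) pairs
give bit-identical datasets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CHANNELS,
    Chromatogram,
    FingerprintMatrix,
    GeneratedDataset,
    SequenceDesign,
)

# stable stream keys: rng = default_rng([seed, TAG, *extra])
_TAG_SEQ = 101
_TAG_DRIFT = 102
_TAG_LOT = 103
_TAG_INJ = 104
_TAG_MIX = 105

#: External class labels (what the classifier sees).
EXTERNAL_CLASSES = ("black", "green", "oolong", "red", "white", "chicory")

#: Class counts of the emulated study (107 samples in total).
DEFAULT_CLASS_COUNTS = {
    "black": 35,
    "green": 20,
    "oolong": 10,
    "red": 12,
    "white": 10,
    "chicory": 20,
}

GRID_START_MIN = 0.0
GRID_END_MIN = 25.0
GRID_STEP_MIN = 0.01


def time_grid(step: float = GRID_STEP_MIN) -> np.ndarray:
    """Retention-time grid in minutes over the 0-25 min run."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((GRID_END_MIN - GRID_START_MIN) / step)) + 1
    return GRID_START_MIN + step * np.arange(n)


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak: Gaussian center, width and amplitudes."""

    rt_min: float
    width_min: float
    amp_uv: float
    amp_fld: float

    def __post_init__(self) -> None:
        if not (GRID_START_MIN <= self.rt_min <= GRID_END_MIN):
            raise ValueError("rt_min must lie in the 0-25 min run")
        if self.width_min <= 0:
            raise ValueError("width_min must be positive")
        if self.amp_uv < 0 or self.amp_fld < 0:
            raise ValueError("amplitudes must be non-negative")

    def amp(self, channel: str) -> float:
        return self.amp_uv if channel == "uv" else self.amp_fld


@dataclass(frozen=True)
class ClassTemplate:
    """Peak pattern of one sample class plus its lot-level variability.

    ``amp_cv`` is the lot-to-lot lognormal coefficient of variation of
    each peak amplitude (different commercial lots of the same product);
    ``rt_jitter_sd`` is the per-injection retention-shift s.d. in
    minutes.  ``white_a``/``white_b`` both carry the external label
    ``white``.
    """

    class_name: str
    peaks: tuple
    amp_cv: float = 0.05
    rt_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.amp_cv < 0 or self.rt_jitter_sd < 0:
            raise ValueError("amp_cv and rt_jitter_sd must be non-negative")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    @property
    def external_label(self) -> str:
        if self.class_name in ("white_a", "white_b"):
            return "white"
        return self.class_name

    def max_amp(self, channel: str) -> float:
        amps = [p.amp(channel) for p in self.peaks]
        return max(amps) if amps else 0.0

    def n_peaks(self, channel: str) -> int:
        return sum(1 for p in self.peaks if p.amp(channel) > 0)


@dataclass(frozen=True)
class DriftModel:
    """Multiplicative detector-sensitivity drift across the sequence.

    Sensitivity at 1-based injection i of an n-injection sequence is
    ``s(i) = (1 + slope * (i - 1) / (n - 1)) * exp(w_i)`` with ``w`` a
    seeded Gaussian random walk of step s.d. ``walk_sd``, emulating a
    slow lamp-intensity decline plus wander.
    """

    slope: float = -0.15
    walk_sd: float = 0.005

    def factors(self, n_injections: int, seed: int) -> np.ndarray:
        if n_injections < 1:
            raise ValueError("need at least one injection")
        rng = np.random.default_rng([seed, _TAG_DRIFT])
        steps = rng.normal(0.0, self.walk_sd, n_injections)
        steps[0] = 0.0
        walk = np.cumsum(steps)
        denom = max(n_injections - 1, 1)
        i = np.arange(n_injections)
        fac = (1.0 + self.slope * i / denom) * np.exp(walk)
        if np.any(fac <= 0):
            raise ValueError("drift slope drives sensitivity non-positive")
        return fac


def _tea_peaks(rts, widths, uvs, flds):
    return tuple(
        PeakSpec(rt, w, uv, fld) for rt, w, uv, fld in zip(rts, widths, uvs, flds)
    )


def build_default_templates() -> dict:
    """Default class templates with the study's qualitative structure.

    Each class carries a crowded, fingerprint-like peak pattern over the
    1-19 min elution window, as untargeted tea/chicory chromatograms
    show.  Amplitudes are arbitrary detector units chosen so that:
    chicory's strongest UV peak is 100-fold weaker than the weakest
    tea's strongest UV peak; white tea dominates UV intensity; black
    and green dominate FLD intensity and carry the most UV peaks among
    teas; red and chicory carry the most FLD peaks; all teas share an
    intense marker peak at 11.0 min; the second white sub-type adds a
    chicory-like side pattern.
    """
    templates = {}
    # black: 22 UV / 14 FLD peaks, max UV 600, max FLD 640
    templates["black"] = ClassTemplate(
        "black",
        _tea_peaks(
            [1.96, 2.81, 3.16, 3.51, 5.40, 5.75, 6.10, 7.36, 7.71, 8.42, 9.33,
             9.68, 10.12, 11.00, 13.55, 14.72, 15.75, 16.28, 17.02, 17.37, 17.72, 18.07],
            [0.06, 0.09, 0.06, 0.12, 0.07, 0.07, 0.08, 0.07, 0.06, 0.06, 0.06,
             0.09, 0.07, 0.12, 0.08, 0.11, 0.09, 0.08, 0.10, 0.11, 0.11, 0.11],
            [417, 298, 427, 121, 312, 323, 106, 426, 109, 175, 134,
             427, 121, 600, 296, 256, 427, 136, 414, 380, 382, 249],
            [478, 310, 0, 462, 430, 0, 131, 382, 0, 160, 0,
             209, 0, 640, 525, 0, 572, 0, 249, 0, 528, 574],
        ),
    )
    # green: 20 UV / 13 FLD peaks, max UV 550, max FLD 600
    templates["green"] = ClassTemplate(
        "green",
        _tea_peaks(
            [1.38, 2.75, 3.71, 4.27, 5.72, 6.07, 6.42, 7.22, 8.28, 8.63,
             10.53, 11.00, 12.38, 12.81, 13.16, 13.51, 14.35, 15.34, 17.76, 18.11],
            [0.08, 0.08, 0.07, 0.08, 0.06, 0.10, 0.08, 0.10, 0.11, 0.09,
             0.10, 0.08, 0.07, 0.08, 0.12, 0.10, 0.06, 0.09, 0.12, 0.07],
            [328, 391, 137, 102, 195, 73, 269, 169, 259, 122,
             381, 550, 290, 231, 276, 157, 340, 138, 192, 389],
            [550, 0, 431, 182, 0, 501, 289, 0, 200, 0,
             266, 600, 0, 465, 532, 546, 0, 525, 0, 194],
        ),
    )
    # oolong: 13 UV / 13 FLD peaks, max UV 450
    templates["oolong"] = ClassTemplate(
        "oolong",
        _tea_peaks(
            [1.87, 2.65, 3.19, 3.78, 4.13, 4.48, 6.65, 11.00, 11.81, 14.13, 14.85, 15.81, 17.01],
            [0.08, 0.10, 0.09, 0.10, 0.10, 0.08, 0.07, 0.11, 0.09, 0.10, 0.09, 0.11, 0.10],
            [198, 137, 104, 310, 110, 62, 268, 450, 134, 160, 97, 292, 276],
            [84, 131, 240, 188, 220, 173, 50, 272, 111, 114, 158, 114, 140],
        ),
    )
    # red (pu-erh): 13 UV / 20 FLD peaks; peak-rich FLD fingerprint
    templates["red"] = ClassTemplate(
        "red",
        _tea_peaks(
            [3.16, 6.38, 7.00, 7.79, 8.14, 8.49, 8.84, 9.23, 9.95, 10.30,
             11.00, 12.75, 13.51, 13.94, 14.43, 14.78, 15.61, 15.96, 16.71, 18.41],
            [0.10, 0.11, 0.10, 0.10, 0.11, 0.12, 0.10, 0.07, 0.10, 0.07,
             0.11, 0.09, 0.08, 0.08, 0.10, 0.07, 0.12, 0.07, 0.10, 0.10],
            [0, 233, 0, 50, 184, 118, 293, 0, 90, 0,
             400, 288, 0, 0, 72, 0, 189, 140, 208, 256],
            [97, 259, 121, 197, 263, 190, 276, 276, 181, 173,
             304, 250, 68, 122, 201, 201, 207, 267, 120, 165],
        ),
    )
    # white_a: 13 UV / 13 FLD peaks, the most intense UV profiles
    templates["white_a"] = ClassTemplate(
        "white_a",
        _tea_peaks(
            [2.45, 3.80, 4.15, 4.61, 11.00, 12.70, 13.19, 13.54, 14.19, 15.14, 15.49, 15.96, 17.25],
            [0.11, 0.10, 0.08, 0.08, 0.09, 0.09, 0.10, 0.11, 0.11, 0.09, 0.09, 0.10, 0.11],
            [716, 414, 589, 160, 1000, 719, 399, 158, 697, 733, 649, 351, 218],
            [129, 71, 255, 52, 304, 66, 177, 276, 49, 229, 200, 216, 223],
        ),
    )
    # white_b: white backbone plus three chicory-like side peaks
    templates["white_b"] = ClassTemplate(
        "white_b",
        _tea_peaks(
            [1.75, 3.27, 4.24, 4.63, 5.47, 6.20, 9.57, 11.00, 12.20, 12.71, 15.97, 16.32,
             4.61, 6.78, 15.62],
            [0.12, 0.09, 0.07, 0.11, 0.09, 0.11, 0.11, 0.09, 0.09, 0.10, 0.11, 0.06,
             0.11, 0.12, 0.10],
            [228, 648, 479, 156, 501, 127, 642, 900, 137, 328, 113, 638,
             6, 5, 4],
            [270, 77, 64, 49, 143, 207, 72, 288, 234, 123, 252, 242,
             180, 160, 140],
        ),
    )
    # chicory: 26 peaks in both channels; UV 100-fold below the teas
    templates["chicory"] = ClassTemplate(
        "chicory",
        _tea_peaks(
            [1.43, 1.91, 2.35, 2.70, 3.05, 3.66, 4.61, 5.38, 6.24, 6.78, 7.90, 8.25, 8.60,
             9.22, 10.35, 11.27, 12.91, 13.63, 14.57, 14.92, 15.27, 15.62, 15.97, 17.02, 18.43, 18.78],
            [0.09, 0.10, 0.08, 0.11, 0.10, 0.07, 0.11, 0.10, 0.08, 0.12, 0.11, 0.11, 0.08,
             0.10, 0.11, 0.08, 0.08, 0.07, 0.11, 0.10, 0.11, 0.10, 0.10, 0.11, 0.10, 0.12],
            [2.47, 1.21, 2.16, 1.83, 0.83, 1.71, 2.33, 1.29, 2.30, 2.46, 2.13, 1.69, 1.69,
             1.94, 0.63, 2.46, 1.82, 1.32, 1.80, 2.26, 1.13, 0.78, 3.50, 0.83, 1.97, 1.31],
            [160, 169, 93, 134, 70, 169, 91, 84, 122, 212, 217, 190, 65,
             151, 91, 226, 130, 139, 145, 64, 134, 320, 235, 130, 40, 146],
        ),
    )
    return templates


@dataclass
class GeneratorConfig:
    """Study conditions of the default simulation."""

    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    grid_step: float = GRID_STEP_MIN
    noise_frac: float = 0.005  # white-noise s.d. as fraction of class max amp
    baseline_frac: float = 0.02  # baseline amplitude as fraction of class max amp
    drift: DriftModel = field(default_factory=DriftModel)
    #: explicit per-injection sensitivity factors; overrides ``drift``
    drift_factors: np.ndarray | None = None
    template_overrides: dict = field(default_factory=dict)
    amp_cv: float | None = None  # override every template's amp_cv
    rt_jitter_sd: float | None = None  # override every template's rt_jitter_sd


# ---------------------------------------------------------------------------
# trace synthesis


def _gaussian_sum(time, peaks, channel, amp_factors=None, rt_shift=0.0):
    trace = np.zeros_like(time)
    for k, peak in enumerate(peaks):
        amp = peak.amp(channel)
        if amp_factors is not None:
            amp = amp * amp_factors[k]
        if amp == 0:
            continue
        trace += amp * np.exp(
            -0.5 * ((time - peak.rt_min - rt_shift) / peak.width_min) ** 2
        )
    return trace


def _lot_factors(template: ClassTemplate, rng) -> np.ndarray:
    """Per-peak lognormal amplitude factors with mean 1 and CV amp_cv."""
    if template.amp_cv == 0:
        return np.ones(len(template.peaks))
    sigma = math.sqrt(math.log(1.0 + template.amp_cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, len(template.peaks)))


def _baseline(time, amp, rng):
    """Smooth low-frequency baseline: two positive cosine humps."""
    if amp == 0:
        return np.zeros_like(time)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    span = GRID_END_MIN - GRID_START_MIN
    b = 0.5 * (1 + np.cos(2 * np.pi * time / span + ph1))
    b += 0.5 * 0.5 * (1 + np.cos(2 * np.pi * time / (0.39 * span) + ph2))
    return amp * b


def _realize(ideal, drift_factor, baseline, noise_sd, rng):
    trace = drift_factor * (ideal + baseline)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, ideal.size)
    return trace


def generate_chromatogram(
    template: ClassTemplate,
    channel: str,
    injection_index: int,
    drift: DriftModel | None = None,
    seed: int = 0,
    *,
    n_injections: int | None = None,
    grid_step: float = GRID_STEP_MIN,
    noise_frac: float = 0.005,
    baseline_frac: float = 0.02,
    amp_factors: np.ndarray | None = None,
    drift_factor: float | None = None,
) -> Chromatogram:
    """Realize one injection of ``template`` on ``channel``.

    The trace is ``s(i) * (Gaussian peak sum with lot amplitude factors
    and a per-injection retention shift, plus a smooth baseline)`` with
    additive white noise.  ``amp_factors`` fixes the lot; otherwise a
    fresh lot is drawn from the seed.  ``drift_factor`` short-circuits
    the drift model with an explicit sensitivity value.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if injection_index < 1:
        raise ValueError("injection_index is 1-based")
    time = time_grid(grid_step)
    rng = np.random.default_rng([seed, _TAG_INJ, injection_index])
    if amp_factors is None:
        amp_factors = _lot_factors(template, np.random.default_rng([seed, _TAG_LOT]))
    rt_shift = (
        rng.normal(0.0, template.rt_jitter_sd) if template.rt_jitter_sd > 0 else 0.0
    )
    ideal = _gaussian_sum(time, template.peaks, channel, amp_factors, rt_shift)
    if drift_factor is None:
        if drift is None:
            drift_factor = 1.0
        else:
            n = n_injections if n_injections is not None else injection_index
            drift_factor = drift.factors(n, seed)[injection_index - 1]
    max_amp = template.max_amp(channel)
    baseline = _baseline(time, baseline_frac * max_amp, rng)
    trace = _realize(ideal, drift_factor, baseline, noise_frac * max_amp, rng)
    return Chromatogram(time, trace, channel, label=template.class_name)


# ---------------------------------------------------------------------------
# sequence construction


def build_injection_sequence(sample_ids, seed: int = 0) -> SequenceDesign:
    """Randomized injection order with QC/blank insertions.

    A QC opens the sequence; after every ten sample injections (and
    after the final partial block) one blank and one QC follow.
    """
    sample_ids = list(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in sample list")
    rows = []
    if sample_ids:
        rng = np.random.default_rng([seed, _TAG_SEQ])
        order = rng.permutation(len(sample_ids))
        shuffled = [sample_ids[i] for i in order]
        qc_n, blank_n = 1, 0
        rows.append(("qc_01", "qc"))
        for start in range(0, len(shuffled), 10):
            for sid in shuffled[start : start + 10]:
                rows.append((sid, "sample"))
            blank_n += 1
            qc_n += 1
            rows.append((f"blank_{blank_n:02d}", "blank"))
            rows.append((f"qc_{qc_n:02d}", "qc"))
    entries = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(rows) + 1),
            "sample_id": [r[0] for r in rows],
            "role": [r[1] for r in rows],
        }
    )
    return SequenceDesign(entries)


# ---------------------------------------------------------------------------
# dataset assembly


def _sample_ids_and_subtypes(class_counts: dict):
    """Stable sample ids plus the (sub-)template each sample draws from."""
    ids, subtypes = [], {}
    for cls in EXTERNAL_CLASSES:
        n = int(class_counts.get(cls, 0))
        if n < 0:
            raise ValueError("class counts must be non-negative")
        for k in range(n):
            sid = f"{cls}_{k + 1:02d}"
            ids.append(sid)
            if cls == "white":
                # split white lots across the two sub-types
                subtypes[sid] = "white_a" if k < (n + 1) // 2 else "white_b"
            else:
                subtypes[sid] = cls
    return ids, subtypes


def make_pooled_qc(samples: FingerprintMatrix) -> np.ndarray:
    """Pooled-QC ideal trace: unweighted mean of the sample traces."""
    if samples.X.shape[0] == 0:
        raise ValueError("cannot pool an empty sample set")
    return samples.X.mean(axis=0)


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0) -> GeneratedDataset:
    """Simulate the full two-channel study for one seed.

    The default configuration emits 107 sample injections per channel
    (35/20/10/12/10/20 across black/green/oolong/red/white/chicory, the
    white lots split 5 + 5 over the two sub-types), framed by 12 QCs and
    11 blanks.
    """
    config = config if config is not None else GeneratorConfig()
    templates = build_default_templates()
    templates.update(config.template_overrides)
    if config.amp_cv is not None:
        templates = {k: replace(v, amp_cv=config.amp_cv) for k, v in templates.items()}
    if config.rt_jitter_sd is not None:
        templates = {
            k: replace(v, rt_jitter_sd=config.rt_jitter_sd) for k, v in templates.items()
        }

    ids, subtypes = _sample_ids_and_subtypes(config.class_counts)
    sequence = build_injection_sequence(ids, seed)
    n_inj = len(sequence)
    time = time_grid(config.grid_step)

    if config.drift_factors is not None:
        factors = np.asarray(config.drift_factors, dtype=float)
        if factors.size != n_inj:
            raise ValueError("drift_factors length must equal the sequence length")
        if np.any(factors <= 0):
            raise ValueError("sensitivity factors must be positive")
    elif n_inj:
        factors = config.drift.factors(n_inj, seed)
    else:
        factors = np.zeros(0)

    # lot-level ideal traces per sample, shared amplitude factors across channels
    ideal_by_sample = {}
    for ordinal, sid in enumerate(ids):
        tpl = templates[subtypes[sid]]
        lot = _lot_factors(tpl, np.random.default_rng([seed, _TAG_LOT, ordinal]))
        ideal_by_sample[sid] = {
            ch: _gaussian_sum(time, tpl.peaks, ch, lot) for ch in CHANNELS
        }

    qc_ideal = {}
    for ch in CHANNELS:
        if ids:
            qc_ideal[ch] = np.mean([ideal_by_sample[s][ch] for s in ids], axis=0)
        else:
            qc_ideal[ch] = np.zeros_like(time)

    default_jitter = (
        np.mean([templates[subtypes[s]].rt_jitter_sd for s in ids]) if ids else 0.0
    )

    matrices, ideals = {}, {}
    meta = sequence.entries.copy()
    meta["class_label"] = [
        templates[subtypes[s]].external_label if r == "sample" else ""
        for s, r in zip(meta["sample_id"], meta["role"])
    ]
    for ch in CHANNELS:
        X = np.zeros((n_inj, time.size))
        ideal_rows = np.zeros_like(X)
        for row, (inj, sid, role) in enumerate(
            sequence.entries[["injection_index", "sample_id", "role"]].itertuples(
                index=False
            )
        ):
            rng = np.random.default_rng([seed, _TAG_INJ, int(inj), _chan_key(ch)])
            # retention shift shared across channels (serial detectors)
            rng_shift = np.random.default_rng([seed, _TAG_INJ, int(inj)])
            if role == "sample":
                tpl = templates[subtypes[sid]]
                ordinal = ids.index(sid)
                lot = _lot_factors(
                    tpl, np.random.default_rng([seed, _TAG_LOT, ordinal])
                )
                shift = (
                    rng_shift.normal(0.0, tpl.rt_jitter_sd)
                    if tpl.rt_jitter_sd > 0
                    else 0.0
                )
                ideal = _gaussian_sum(time, tpl.peaks, ch, lot, shift)
                ref_amp = tpl.max_amp(ch)
                ideal_rows[row] = ideal_by_sample[sid][ch]
            elif role == "qc":
                shift = (
                    rng_shift.normal(0.0, default_jitter) if default_jitter > 0 else 0.0
                )
                ideal = _shift_trace(time, qc_ideal[ch], shift)
                ref_amp = float(qc_ideal[ch].max()) if qc_ideal[ch].size else 0.0
                ideal_rows[row] = qc_ideal[ch]
            else:  # blank: mineral water, baseline + noise only
                ideal = np.zeros_like(time)
                ref_amp = float(qc_ideal[ch].max()) if qc_ideal[ch].size else 0.0
            baseline = _baseline(time, config.baseline_frac * ref_amp, rng)
            X[row] = _realize(
                ideal, factors[row], baseline, config.noise_frac * ref_amp, rng
            )
        matrices[ch] = FingerprintMatrix(time=time, X=X, meta=meta.copy(), channel=ch)
        ideals[ch] = ideal_rows

    truth = pd.DataFrame(
        {
            "sample_id": ids,
            "class_label": [templates[subtypes[s]].external_label for s in ids],
            "subtype": [subtypes[s] for s in ids],
        }
    )
    return GeneratedDataset(
        uv=matrices["uv"],
        fld=matrices["fld"],
        sequence=sequence,
        truth=truth,
        ideal=ideals,
        templates=templates,
        config=config,
    )


def _chan_key(channel: str) -> int:
    return 1 if channel == "uv" else 2


def _shift_trace(time, trace, shift_min):
    if shift_min == 0:
        return trace.copy()
    return np.interp(time - shift_min, time, trace)


# ---------------------------------------------------------------------------
# in-silico mixtures


def mix_fingerprints(
    tea: Chromatogram,
    chicory: Chromatogram,
    adulterant_pct: float,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_key: int = 0,
) -> Chromatogram:
    """Linear in-silico blend: (1 - p/100) * tea + (p/100) * chicory.

    Detector response is additive at these concentrations, so blending
    intensities mirrors blending extracts.  ``noise_sd`` adds a fresh
    white-noise realization keyed by ``noise_key``.
    """
    if not (0.0 <= adulterant_pct <= 100.0):
        raise ValueError("adulterant percentage must be in [0, 100]")
    if tea.channel != chicory.channel:
        raise ValueError("channel mismatch between tea and chicory traces")
    if not np.array_equal(tea.time, chicory.time):
        raise ValueError("tea and chicory must share the time grid")
    p = adulterant_pct / 100.0
    mixed = (1.0 - p) * tea.intensity + p * chicory.intensity
    if noise_sd > 0:
        rng = np.random.default_rng([seed, _TAG_MIX, noise_key])
        mixed = mixed + rng.normal(0.0, noise_sd, mixed.size)
    return Chromatogram(
        tea.time, mixed, tea.channel, label=f"{tea.label}+{chicory.label}@{adulterant_pct:g}"
    )
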