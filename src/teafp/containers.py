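"""In-memory containers shared across the pipeline.

A *fingerprint* is the full detector trace (intensity versus retention
time) of one injection, used whole as the feature vector.  The pipeline
never detects or integrates peaks; all chemometrics operate on the
fingerprint matrix directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised detection channels: UV absorbance at 280 nm and
#: fluorescence (280 nm excitation / 350 nm emission).
CHANNELS = ("uv", "fld")

#: Injection roles in an analytical sequence.
ROLES = ("sample", "qc", "blank")


@dataclass(frozen=True)
class Chromatogram:
    """One injection's intensity trace on a shared retention-time grid."""

    time: np.ndarray
    intensity: np.ndarray
    channel: str
    label: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if time.ndim != 1 or intensity.ndim != 1:
            raise ValueError("time and intensity must be 1-D")
        if time.shape != intensity.shape:
            raise ValueError("time and intensity lengths differ")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class SequenceDesign:
    """Ordered injection sequence: (1-based index, sample id, role).

    Invariants: indices are 1..n gapless, a QC opens the sequence, and a
    blank + QC pair follows each block of ten sample injections.
    """

    entries: pd.DataFrame  # columns: injection_index, sample_id, role

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries, copy=True)
        required = {"injection_index", "sample_id", "role"}
        if not required.issubset(df.columns):
            raise ValueError(f"sequence needs columns {sorted(required)}")
        df = df.reset_index(drop=True)
        idx = df["injection_index"].to_numpy()
        if len(df) and not np.array_equal(idx, np.arange(1, len(df) + 1)):
            raise ValueError("injection_index must be 1..n, gapless")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def roles(self) -> np.ndarray:
        return self.entries["role"].to_numpy()

    @property
    def qc_indices(self) -> np.ndarray:
        """1-based injection indices of the QC injections."""
        return self.entries.loc[
            self.entries["role"] == "qc", "injection_index"
        ].to_numpy()

    def nearest_qc(self, injection_index: int) -> int:
        """Injection index of the QC nearest to ``injection_index``.

        Ties are broken toward the preceding QC; a QC always opens the
        sequence so a preceding QC always exists.
        """
        qcs = self.qc_indices
        if qcs.size == 0:
            raise ValueError("sequence contains no QC injections")
        dist = np.abs(qcs - injection_index)
        # stable argmin prefers the earlier (preceding) QC on ties
        return int(qcs[np.argmin(dist)])


@dataclass
class FingerprintMatrix:
    """Injections x time-points matrix with aligned injection metadata.

    ``meta`` rows correspond one-to-one to rows of ``X`` and carry
    sample_id, class_label, injection_index and role, ordered by
    injection_index.
    """

    time: np.ndarray
    X: np.ndarray
    meta: pd.DataFrame
    channel: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (injections x time points)")
        if self.X.shape[1] != self.time.size:
            raise ValueError("X column count must match time grid length")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta row count must match X row count")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_injections(self) -> int:
        return self.X.shape[0]

    def rows(self, mask: np.ndarray) -> "FingerprintMatrix":
        """Sub-matrix of the rows selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return FingerprintMatrix(
            time=self.time,
            X=self.X[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            channel=self.channel,
        )

    def samples_only(self) -> "FingerprintMatrix":
        return self.rows((self.meta["role"] == "sample").to_numpy())

    def copy(self) -> "FingerprintMatrix":
        return FingerprintMatrix(
            time=self.time.copy(),
            X=self.X.copy(),
            meta=self.meta.copy(),
            channel=self.channel,
        )


@dataclass
class GeneratedDataset:
    """A simulated two-channel study: realized matrices plus ground truth.

    ``ideal`` holds the drift-, noise- and jitter-free trace of every
    injection (the underlying extract fingerprint); mixture building and
    pooled-QC checks read these, the chemometrics never do.
    """

    uv: FingerprintMatrix
    fld: FingerprintMatrix
    sequence: SequenceDesign
    truth: pd.DataFrame  # sample_id, class_label, subtype
    ideal: dict = field(default_factory=dict)  # channel -> (n, p) array
    templates: dict = field(default_factory=dict)  # name -> ClassTemplate
    config: object = None

    def __post_init__(self) -> None:
        if not np.array_equal(self.uv.time, self.fld.time):
            raise ValueError("uv and fld must share the time grid")
        if len(self.uv.meta) != len(self.fld.meta):
            raise ValueError("uv and fld must share the injection sequence")

    def channel(self, name: str) -> FingerprintMatrix:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        return self.uv if name == "uv" else self.fld
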