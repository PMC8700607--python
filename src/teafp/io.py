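"""File formats and run configuration.

Chromatogram sets are stored as one wide CSV per detection channel:
column 1 is ``time_min`` (uniform, increasing), then one intensity
column per injection named by its sample id.  Injection metadata lives
in a separate CSV (sample_id, class_label, injection_index, role).
Values are written at nine significant digits, so a round trip
preserves the matrix to relative 1e-9.  Run configuration is a YAML
key/value file with unknown keys rejected.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FingerprintMatrix, GeneratedDataset, SequenceDesign
from .preprocess import PreprocessConfig
from .synthetic import DriftModel, GeneratorConfig
from .adulteration import MixtureDesign


class FormatError(ValueError):
    """Raised for any file-schema violation; carries an error code."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


# ---------------------------------------------------------------------------
# chromatogram set + metadata CSVs


def write_chromatogram_set(matrix: FingerprintMatrix, path) -> None:
    path = Path(path)
    cols = {"time_min": matrix.time}
    ids = matrix.meta["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate-ids", "sample ids must be unique")
    for sid, row in zip(ids, matrix.X):
        cols[sid] = row
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.9g")


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta[["sample_id", "class_label", "injection_index", "role"]].copy()
    out.loc[out["role"] != "sample", "class_label"] = ""
    out.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    required = {"sample_id", "class_label", "injection_index", "role"}
    if not required.issubset(meta.columns):
        raise FormatError("metadata-schema", f"need columns {sorted(required)}")
    if meta["injection_index"].duplicated().any():
        raise FormatError("duplicate-injection", "injection_index must be unique")
    return meta.sort_values("injection_index").reset_index(drop=True)


def read_chromatogram_set(csv_path, metadata_path, channel: str) -> FingerprintMatrix:
    """Load one channel's wide CSV; rows ordered by injection_index."""
    df = pd.read_csv(csv_path)
    if "time_min" not in df.columns:
        raise FormatError("missing-time", "first column must be time_min")
    time = df["time_min"].to_numpy(dtype=float)
    if time.size > 1:
        steps = np.diff(time)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise FormatError("grid", "time_min must increase on a uniform grid")
    if df.isna().any().any():
        raise FormatError("missing-cells", "chromatogram CSV contains missing cells")
    meta = read_metadata(metadata_path)
    data_cols = [c for c in df.columns if c != "time_min"]
    if len(set(data_cols)) != len(data_cols):
        raise FormatError("duplicate-ids", "duplicate injection columns")
    missing = set(data_cols) - set(meta["sample_id"])
    if missing:
        raise FormatError(
            "missing-metadata", f"no metadata rows for {sorted(missing)}"
        )
    extra = set(meta["sample_id"]) - set(data_cols)
    if extra:
        raise FormatError(
            "missing-columns", f"metadata rows without chromatograms: {sorted(extra)}"
        )
    X = np.stack([df[sid].to_numpy(dtype=float) for sid in meta["sample_id"]])
    return FingerprintMatrix(time=time, X=X, meta=meta, channel=channel)


def write_dataset(dataset: GeneratedDataset, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "uv": outdir / "uv.csv",
        "fld": outdir / "fld.csv",
        "metadata": outdir / "metadata.csv",
    }
    write_chromatogram_set(dataset.uv, paths["uv"])
    write_chromatogram_set(dataset.fld, paths["fld"])
    write_metadata(dataset.uv.meta, paths["metadata"])
    return paths


def read_dataset(indir) -> GeneratedDataset:
    indir = Path(indir)
    uv = read_chromatogram_set(indir / "uv.csv", indir / "metadata.csv", "uv")
    fld = read_chromatogram_set(indir / "fld.csv", indir / "metadata.csv", "fld")
    sequence = SequenceDesign(uv.meta[["injection_index", "sample_id", "role"]])
    samples = uv.meta[uv.meta["role"] == "sample"]
    truth = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "class_label": samples["class_label"].to_numpy(),
            "subtype": samples["class_label"].to_numpy(),
        }
    )
    return GeneratedDataset(uv=uv, fld=fld, sequence=sequence, truth=truth)


# ---------------------------------------------------------------------------
# run configuration


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise FormatError("config-key", f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path) -> dict:
    """Parse a YAML run configuration into typed sections.

    Sections: seed (int), generator (GeneratorConfig fields, drift given
    as {slope, walk_sd}), preprocess (PreprocessConfig fields), cv
    ({max_lv, n_splits, rel_tol}), mixture_design (MixtureDesign
    fields).  Unknown keys anywhere are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"seed", "generator", "preprocess", "cv", "mixture_design"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError("config-key", f"unknown top-level keys: {sorted(unknown)}")
    out = {"seed": int(raw.get("seed", 0))}
    gen = dict(raw.get("generator", {}))
    if "drift" in gen:
        gen["drift"] = _from_dict(DriftModel, dict(gen["drift"]))
    out["generator"] = _from_dict(GeneratorConfig, gen)
    out["preprocess"] = _from_dict(PreprocessConfig, dict(raw.get("preprocess", {})))
    cv = dict(raw.get("cv", {}))
    unknown = set(cv) - {"max_lv", "n_splits", "rel_tol"}
    if unknown:
        raise FormatError("config-key", f"unknown cv keys: {sorted(unknown)}")
    out["cv"] = {"max_lv": 8, "n_splits": 10, "rel_tol": 0.02, **cv}
    md = dict(raw.get("mixture_design", {}))
    if md:
        md = {k: tuple(v) if isinstance(v, list) else v for k, v in md.items()}
    out["mixture_design"] = _from_dict(MixtureDesign, md)
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(config, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# JSON-lines run log


class RunLog:
    """Append-only JSON-lines log of pipeline stages and timings."""

    def __init__(self, path, command: str, seed: int, cfg_hash: str = ""):
        self.path = Path(path)
        self.command = command
        self.seed = seed
        self.cfg_hash = cfg_hash
        self._t0 = _time.perf_counter()
        self.write({"event": "start"})

    def write(self, record: dict) -> None:
        record = {
            "command": self.command,
            "seed": self.seed,
            "config_hash": self.cfg_hash,
            "elapsed_s": round(_time.perf_counter() - self._t0, 4),
            **record,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record) + "\n")

    def stage(self, name: str, **extra) -> None:
        self.write({"event": "stage", "stage": name, **extra})
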