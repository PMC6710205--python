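"""Readers and writers for waveforms, subject tables, volumes and reports.

CSV/TSV for time series and tables, JSON for models and provenance,
NIfTI (via nibabel) for volumes.  All writes are atomic
(write-to-temporary, then rename) and every report embeds the config
hash and seed that produced it.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import WaveformRecord

WAVEFORM_COLUMNS = {"time_s": "time", "abp_mmHg": "abp",
                    "cbfv_cms": "cbfv", "co2_mmHg": "co2"}


def _atomic_write(path, writer):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_waveforms(record: WaveformRecord, path) -> None:
    df = pd.DataFrame({"time_s": record.time, "abp_mmHg": record.abp,
                       "cbfv_cms": record.cbfv, "co2_mmHg": record.co2})
    # %.17g round-trips float64 exactly
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False,
                                              float_format="%.17g"))


def read_waveforms(path) -> WaveformRecord:
    """Load a waveform CSV/TSV; infer fs from the time column.

    The time column must be strictly increasing and uniform within 1%.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"waveform file missing column(s): {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column is not strictly increasing")
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise ValueError("sampling is not uniform within 1%")
    return WaveformRecord(fs=1.0 / step, time=t,
                          abp=df["abp_mmHg"].to_numpy(dtype=float),
                          cbfv=df["cbfv_cms"].to_numpy(dtype=float),
                          co2=df["co2_mmHg"].to_numpy(dtype=float))


def read_subject_table(path) -> pd.DataFrame:
    """Load a per-subject marker/score table with validation.

    Requires id, group (CS|MP), age, gender, education columns; any
    further columns are markers/scores.  Empty cells stay NaN and are
    handled pairwise-complete downstream.
    """
    df = pd.read_csv(path)
    required = ["id", "group", "age", "gender", "education"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing column(s): {missing}")
    bad = set(df["group"].unique()) - {"CS", "MP"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate subject id(s): {dup}")
    return df


def write_subject_table(table: pd.DataFrame, path) -> None:
    _atomic_write(path, lambda tmp: table.to_csv(tmp, index=False))


def write_report(results: dict, path, config=None, seed=None) -> None:
    """Write an analysis report as JSON with embedded provenance.

    DataFrames and arrays inside ``results`` are converted to plain
    structures; the config hash and seed make the run reproducible.
    """
    def convert(obj):
        if isinstance(obj, pd.DataFrame):
            # manual split-orient conversion: json.dumps of native floats
            # round-trips exactly, unlike to_json's fixed precision
            return {"columns": [str(c) for c in obj.columns],
                    "data": [[convert(v) for v in row]
                             for row in obj.itertuples(index=False)]}
        if isinstance(obj, (np.ndarray, pd.Series)):
            return np.asarray(obj).tolist()
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    payload = {"provenance": {
        "config_hash": config.hash() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
    }, "results": convert(results)}
    _atomic_write(path, lambda tmp: Path(tmp).write_text(
        json.dumps(payload, indent=2, allow_nan=True)))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_volume(data, path, affine=None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          affine if affine is not None else np.eye(4))
    _atomic_write(path, lambda tmp: nib.save(img, tmp + ".nii.gz") or
                  os.replace(tmp + ".nii.gz", tmp))


def read_volume(path):
    img = nib.load(path)
    return np.asarray(img.get_fdata()), img.affine


def write_voxel_dataset(volumes, mask, labels, out_dir, truth_mask=None,
                        meta=None) -> None:
    """Write per-subject metric volumes, mask and labels as NIfTI + JSON.

    Ground truth (when present) goes into the JSON sidecar so recovered
    masks can be scored against it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, vol in enumerate(np.asarray(volumes)):
        write_volume(vol, out / f"subject_{i:03d}.nii.gz")
    write_volume(np.asarray(mask, dtype=float), out / "mask.nii.gz")
    write_volume(np.asarray(labels, dtype=float), out / "labels.nii.gz")
    sidecar = dict(meta or {})
    sidecar["axis_order"] = "xyz"
    sidecar["indexing"] = "0-based"
    if truth_mask is not None:
        sidecar["truth_mask_voxels"] = np.argwhere(
            np.asarray(truth_mask)).tolist()
    _atomic_write(out / "ground_truth.json", lambda tmp: Path(tmp).write_text(
        json.dumps(sidecar, indent=2)))
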