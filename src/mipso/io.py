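"""Readers and writers for trial containers, feature tables and masks.

Trial tensors live in an HDF5 container with datasets ``X`` (trials x
channels x samples) and ``Y`` (labels) plus a JSON sidecar carrying the
sampling rate and channel names; a plain-text alternative stores one
delimited file per trial.  Feature matrices round-trip through TSV with
``ch{c}_f{f}`` headers and a final ``label`` column.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import FeatureMatrix, TrialTensor
from .multilevel import SelectionMask

__all__ = [
    "write_trials_h5",
    "read_trials_h5",
    "write_trials_text",
    "read_trials_text",
    "write_features_tsv",
    "read_features_tsv",
    "write_mask",
    "read_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trials_h5(path: str | Path, trials: TrialTensor) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=trials.data)
        h5.create_dataset("Y", data=trials.labels)
        h5.attrs["fs"] = trials.fs
    sidecar = {"fs": trials.fs, "channel_names": list(trials.channel_names)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trials_h5(path: str | Path) -> TrialTensor:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        data = np.asarray(h5["X"])
        labels = np.asarray(h5["Y"])
        fs_attr = float(h5.attrs.get("fs", 0.0))
    sidecar = _sidecar_path(path)
    channel_names = None
    fs = fs_attr
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.get("fs", fs_attr))
        channel_names = meta.get("channel_names")
    if fs <= 0:
        raise ValueError(f"no sampling rate found for {path}; provide a JSON sidecar")
    return TrialTensor(data, labels, fs, channel_names)


def write_trials_text(directory: str | Path, trials: TrialTensor) -> None:
    """One TSV per trial (samples as rows, channels as columns) + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(trials.n_trials - 1)))
    for i in range(trials.n_trials):
        frame = pd.DataFrame(trials.data[i].T, columns=trials.channel_names)
        frame.to_csv(directory / f"trial_{i:0{width}d}.tsv", sep="\t", index=False)
    meta = {
        "fs": trials.fs,
        "channel_names": list(trials.channel_names),
        "labels": trials.labels.tolist(),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trials_text(directory: str | Path) -> TrialTensor:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    files = sorted(directory.glob("trial_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no trial_*.tsv files under {directory}")
    data = np.stack(
        [pd.read_csv(f, sep="\t").to_numpy().T for f in files], axis=0
    )
    return TrialTensor(data, np.asarray(meta["labels"]), float(meta["fs"]), meta.get("channel_names"))


def write_features_tsv(path: str | Path, features: FeatureMatrix) -> None:
    features.to_frame().to_csv(Path(path), sep="\t", index=False)


_COL_RE = re.compile(r"^ch(\d+)_f([0-9.]+)$")


def read_features_tsv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(Path(path), sep="\t")
    if "label" not in df.columns:
        raise ValueError("feature table must end with a 'label' column")
    labels = df.pop("label").to_numpy()
    columns = []
    for name in df.columns:
        m = _COL_RE.match(name)
        if not m:
            raise ValueError(f"unparseable feature column name {name!r}")
        columns.append((int(m.group(1)), float(m.group(2))))
    return FeatureMatrix(df.to_numpy(dtype=np.float64), columns, labels)


def write_mask(path: str | Path, mask: SelectionMask) -> None:
    Path(path).write_text(mask.to_text())


def read_mask(path: str | Path) -> SelectionMask:
    bits, provenance = [], []
    granularity = "feature"
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "granularity:" in line:
                granularity = line.split("granularity:")[1].strip()
            continue
        bit, prov = line.split("\t", 1)
        bits.append(int(bit))
        prov = prov.strip()
        if prov.startswith("("):
            ch, f = prov.strip("()").split(",")
            provenance.append((int(ch), float(f)))
        else:
            provenance.append(int(prov))
    return SelectionMask(np.asarray(bits, dtype=np.uint8), granularity, provenance)
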