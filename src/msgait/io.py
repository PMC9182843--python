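"""Dataset readers/writers, checkpoints and run configuration.

Two on-disk dataset formats are supported:

* CSV with columns ``t, Ax, Ay, Az, Gx, Gy, Gz, subject, window_id`` (one row
  per time step);
* a compressed NumPy container (``.npz``) with arrays ``signals``
  ``(n, length, 6)`` and ``labels`` ``(n,)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .network import MultiScaleGaitNet
from .preprocess import CHANNEL_NAMES, InertialWindow
from .synthetic import LabeledDataset

CSV_COLUMNS = ("t", *CHANNEL_NAMES, "subject", "window_id")


def write_csv(dataset: LabeledDataset, path) -> None:
    """Write one row per time step with subject and window ids."""
    frames = []
    for wid, (w, label) in enumerate(zip(dataset.windows, dataset.labels)):
        df = pd.DataFrame(w.values, columns=list(CHANNEL_NAMES))
        df.insert(0, "t", np.arange(w.length))
        df["subject"] = int(label)
        df["window_id"] = wid
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv(path) -> LabeledDataset:
    """Read the CSV layout back; schema violations name the offending part."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} missing columns: {', '.join(missing)}")
    for c in CSV_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            raise ValueError(
                f"CSV {path}: non-numeric entries in column {c!r} at rows "
                f"{bad[:5].tolist()}")
    windows, labels = [], []
    lengths = {}
    for wid, grp in df.groupby("window_id", sort=True):
        lengths[int(wid)] = len(grp)
    if len(set(lengths.values())) > 1:
        common = max(set(lengths.values()),
                     key=lambda L: sum(v == L for v in lengths.values()))
        bad = sorted(w for w, L in lengths.items() if L != common)
        raise ValueError(
            f"CSV {path}: inconsistent window lengths; offending "
            f"window_ids: {bad}")
    for wid, grp in df.groupby("window_id", sort=True):
        grp = grp.sort_values("t")
        label = int(grp["subject"].iloc[0])
        windows.append(InertialWindow(
            grp[list(CHANNEL_NAMES)].to_numpy(dtype=np.float64), label))
        labels.append(label)
    return LabeledDataset(windows, np.array(labels))


def write_npz(dataset: LabeledDataset, path) -> None:
    """Write the compressed-array container (signals + labels)."""
    np.savez_compressed(path, signals=dataset.signals(),
                        labels=dataset.labels)


def read_npz(path) -> LabeledDataset:
    with np.load(path) as data:
        if "signals" not in data or "labels" not in data:
            raise ValueError(
                f"{path}: container must hold 'signals' and 'labels'")
        signals = data["signals"]
        labels = data["labels"]
    windows = [InertialWindow(signals[i], int(labels[i]))
               for i in range(signals.shape[0])]
    return LabeledDataset(windows, labels)


def load_dataset(path, format: Optional[str] = None) -> LabeledDataset:
    """Load a dataset, inferring the format from the extension by default."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "array_container")
    if fmt == "csv":
        return read_csv(path)
    if fmt == "array_container":
        return read_npz(path)
    raise ValueError(f"unknown dataset format {fmt!r}")


def save_dataset(dataset: LabeledDataset, path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        write_csv(dataset, path)
    else:
        write_npz(dataset, path)


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(model: MultiScaleGaitNet, path) -> None:
    """Persist model hyperparameters, weights and Fisher state in one file."""
    meta = {
        "n_classes": model.n_classes,
        "scales": list(model.scales),
        "input_length": model.input_length,
        "fused_dim": model.fused_dim,
        "n_prime": model.n_prime,
        "fisher_momentum": model.fisher_momentum,
        "fusion_dropout": model.fusion_dropout,
        "use_ws": model.use_ws,
        "dropout_rate": model.config.dropout_rate,
        "l2_reg": model.config.l2_reg,
        "layers": [[s.kind, s.kernel_size, s.n_kernels, s.stride, s.padding]
                   for s in model.config.layers],
    }
    arrays = {f"param:{k}": v for k, v in model.params.items()}
    for tau, st in model.fisher.items():
        if st["sw"] is not None:
            arrays[f"fisher:{tau}:sw"] = st["sw"]
            arrays[f"fisher:{tau}:sb"] = st["sb"]
        arrays[f"fisher:{tau}:lambda"] = st["fw"].lambda_
        arrays[f"fisher:{tau}:eigenvectors"] = st["fw"].eigenvectors
        arrays[f"fisher:{tau}:projection"] = st["fw"].projection
        arrays[f"fisher:{tau}:weights"] = st["weights"]
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> MultiScaleGaitNet:
    from .backbone import BackboneConfig, LayerSpec
    from .wsnet import FisherWeights

    with np.load(path) as data:
        meta = json.loads(str(data["meta"]))
        config = BackboneConfig(
            layers=tuple(LayerSpec(*spec) for spec in meta["layers"]),
            dropout_rate=meta["dropout_rate"], l2_reg=meta["l2_reg"])
        model = MultiScaleGaitNet(
            n_classes=meta["n_classes"], scales=meta["scales"],
            input_length=meta["input_length"],
            config=config,
            fused_dim=meta["fused_dim"], n_prime=meta["n_prime"],
            fisher_momentum=meta["fisher_momentum"],
            fusion_dropout=meta["fusion_dropout"], use_ws=meta["use_ws"])
        for key in data.files:
            if key.startswith("param:"):
                model.params[key[len("param:"):]] = data[key]
        for tau in model.scales:
            st = model.fisher[tau]
            if f"fisher:{tau}:sw" in data.files:
                st["sw"] = data[f"fisher:{tau}:sw"]
                st["sb"] = data[f"fisher:{tau}:sb"]
            st["fw"] = FisherWeights(
                data[f"fisher:{tau}:lambda"],
                data[f"fisher:{tau}:eigenvectors"],
                data[f"fisher:{tau}:projection"])
            st["weights"] = data[f"fisher:{tau}:weights"]
    return model


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    scales: tuple = (2, 3, 4, 5)
    window_length: int = 200
    fused_dim: int = 64
    dropout_rate: float = 0.5
    fusion_dropout: float = 0.8
    l2_reg: float = 1e-4
    use_ws: bool = True
    normalize: bool = True
    # training
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 50
    alpha: float = 0.99
    beta: float = 0.87
    val_fraction: float = 0.1
    # data (synthetic generation when data_path is None)
    data_path: Optional[str] = None
    n_subjects: int = 10
    windows_per_subject: int = 40
    noise_sd: float = 0.25
    covariate_kind: str = "none"
    covariate_magnitude: float = 0.0
    probe_fraction: float = 0.25
    # bookkeeping
    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["scales"] = list(self.scales)
        return d


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run config, applying keyword overrides on top."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    if "scales" in raw:
        raw["scales"] = tuple(raw["scales"])
    return RunConfig(**raw)
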