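"""Containers on disk: epoch sets, templates and network checkpoints.

The primary container is HDF5 (datasets ``data`` and ``labels``, attributes
``fs``, ``channel_names``, ``class_names``); a CSV + JSON-sidecar fallback
covers small sets where a text format is preferable.  Round-trips are
lossless for the HDF5 path and float-text exact for CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .augmentation import EpochSet, Template
from .dynamics import FilterParams, NeuronParams
from .network import NetworkSpec, NetworkState, PerturbationConfig
from .training import TrainingRecord

__all__ = [
    "SchemaError",
    "read_epochs",
    "write_epochs",
    "read_template",
    "write_template",
    "save_network",
    "load_network",
]

_HDF5_SUFFIXES = {".h5", ".hdf5"}


class SchemaError(ValueError):
    """A container file is missing a required dataset or attribute."""


def _require(group, kind: str, name: str):
    source = group.attrs if kind == "attribute" else group
    if name not in source:
        raise SchemaError(f"missing {kind} {name!r} in {group.file.filename}")
    return source[name]


def _str_list(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=epochs.data)
            fh.create_dataset("labels", data=epochs.labels)
            fh.attrs["fs"] = epochs.fs
            fh.attrs["channel_names"] = epochs.channel_names
            fh.attrs["class_names"] = epochs.class_names
        return
    # CSV fallback: one row per (trial, channel), JSON sidecar for the rest
    flat = epochs.data.reshape(-1, epochs.n_samples)
    np.savetxt(path, flat, delimiter=",")
    sidecar = {
        "shape": list(epochs.data.shape),
        "labels": epochs.labels.tolist(),
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
        "class_names": epochs.class_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            data = np.asarray(_require(fh, "dataset", "data"))
            labels = np.asarray(_require(fh, "dataset", "labels"))
            fs = float(_require(fh, "attribute", "fs"))
            channels = _str_list(_require(fh, "attribute", "channel_names"))
            classes = _str_list(_require(fh, "attribute", "class_names"))
        return EpochSet(data, labels, fs, channels, classes)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("shape", "labels", "fs", "channel_names", "class_names"):
        if key not in meta:
            raise SchemaError(f"missing field {key!r} in {sidecar_path}")
    data = np.loadtxt(path, delimiter=",", ndmin=2).reshape(meta["shape"])
    return EpochSet(
        data,
        np.asarray(meta["labels"]),
        float(meta["fs"]),
        list(meta["channel_names"]),
        list(meta["class_names"]),
    )


def write_template(template: Template, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signals", data=template.signals)
            fh.attrs["fs"] = template.fs
            fh.attrs["channel_names"] = template.channel_names
            fh.attrs["class_names"] = template.class_names
            fh.attrs["provenance"] = json.dumps(template.provenance)
        return
    np.savetxt(path, template.signals.reshape(-1, template.signals.shape[-1]), delimiter=",")
    sidecar = {
        "shape": list(template.signals.shape),
        "fs": template.fs,
        "channel_names": template.channel_names,
        "class_names": template.class_names,
        "provenance": template.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_template(path: str | Path) -> Template:
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            signals = np.asarray(_require(fh, "dataset", "signals"))
            fs = float(_require(fh, "attribute", "fs"))
            channels = _str_list(_require(fh, "attribute", "channel_names"))
            classes = _str_list(_require(fh, "attribute", "class_names"))
            prov = json.loads(fh.attrs.get("provenance", "{}"))
        return Template(signals, classes, channels, fs, prov)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    signals = np.loadtxt(path, delimiter=",", ndmin=2).reshape(meta["shape"])
    return Template(
        signals,
        list(meta["class_names"]),
        list(meta["channel_names"]),
        float(meta["fs"]),
        meta.get("provenance", {}),
    )


def save_network(net: NetworkState, path: str | Path) -> None:
    """Checkpoint weights, architecture and training metadata to HDF5."""
    spec = net.spec
    with h5py.File(path, "w") as fh:
        for name in ("W_ih", "W_ho", "W_read"):
            fh.create_dataset(name, data=getattr(net, name))
        if net.W_pert is not None:
            fh.create_dataset("W_pert", data=net.W_pert)
            fh.attrs["pert_cfg"] = json.dumps(asdict(net.pert_cfg))
        fh.attrs["spec"] = json.dumps(
            {
                "layer_sizes": list(spec.layer_sizes),
                "n_channels": spec.n_channels,
                "neuron_params": asdict(spec.neuron_params),
                "filter_params": asdict(spec.filter_params),
                "init_scale": spec.init_scale,
                "readout_scale": spec.readout_scale,
                "eeg_fs": spec.eeg_fs,
                "seed": spec.seed,
            }
        )
        if net.training_record is not None:
            rec = net.training_record
            grp = fh.create_group("training")
            grp.create_dataset("loss_history", data=rec.loss_history)
            grp.create_dataset("final_correlation", data=rec.final_correlation)
            grp.attrs["class_names"] = rec.class_names
            grp.attrs["epochs_run"] = rec.epochs_run
            if rec.channel_names is not None:
                grp.attrs["channel_names"] = rec.channel_names


def load_network(path: str | Path) -> NetworkState:
    with h5py.File(path, "r") as fh:
        meta = json.loads(str(_require(fh, "attribute", "spec")))
        spec = NetworkSpec(
            layer_sizes=tuple(meta["layer_sizes"]),
            n_channels=meta["n_channels"],
            neuron_params=NeuronParams(**meta["neuron_params"]),
            filter_params=FilterParams(**meta["filter_params"]),
            init_scale=meta["init_scale"],
            readout_scale=meta["readout_scale"],
            eeg_fs=meta["eeg_fs"],
            seed=meta["seed"],
        )
        net = NetworkState(
            W_ih=np.asarray(_require(fh, "dataset", "W_ih")),
            W_ho=np.asarray(_require(fh, "dataset", "W_ho")),
            W_read=np.asarray(_require(fh, "dataset", "W_read")),
            spec=spec,
        )
        if "W_pert" in fh:
            net.W_pert = np.asarray(fh["W_pert"])
            net.pert_cfg = PerturbationConfig(**json.loads(str(fh.attrs["pert_cfg"])))
        if "training" in fh:
            grp = fh["training"]
            net.training_record = TrainingRecord(
                loss_history=np.asarray(grp["loss_history"]),
                epochs_run=int(grp.attrs["epochs_run"]),
                final_correlation=np.asarray(grp["final_correlation"]),
                class_names=_str_list(grp.attrs["class_names"]),
                channel_names=(
                    _str_list(grp.attrs["channel_names"])
                    if "channel_names" in grp.attrs
                    else None
                ),
            )
    return net
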