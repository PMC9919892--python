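"""Readers and writers for the package's on-disk formats.

Containers: signals and feature batches in NPZ or HDF5 (datasets ``data``,
``fs``, ``labels`` — the schema the synthetic generator and the experiment
harness share); N x N connectivity matrices as CSV with a channel-name
header plus an optional JSON sidecar; model checkpoints as a single NPZ
archive with an embedded JSON config manifest; per-trial CSVs for toy
inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, SignalEpochs
from .exceptions import ParameterError
from .fusion import FusedGraph
from .gcn import ChebGCNClassifier, FeatureBatch, build_spectral_operator


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5"}


def save_signals(signals: SignalEpochs, path: str | Path) -> None:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=signals.data)
            f.create_dataset("fs", data=signals.fs)
            f.create_dataset("labels", data=signals.labels)
    else:
        np.savez(path, data=signals.data, fs=signals.fs, labels=signals.labels)


def load_signals(path: str | Path) -> SignalEpochs:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            return SignalEpochs(
                data=f["data"][()], fs=float(f["fs"][()]), labels=f["labels"][()]
            )
    with np.load(path) as z:
        return SignalEpochs(
            data=z["data"], fs=float(z["fs"]), labels=z["labels"]
        )


def load_signals_csv(
    trial_paths: Sequence[str | Path], fs: float, labels: Sequence[int]
) -> SignalEpochs:
    """Assemble epochs from per-trial CSVs (columns = channels, rows = samples)."""
    if len(trial_paths) != len(labels):
        raise ParameterError("need one label per trial CSV")
    trials = [pd.read_csv(p).to_numpy(dtype=float).T for p in trial_paths]
    shapes = {t.shape for t in trials}
    if len(shapes) != 1:
        raise ParameterError(f"trial CSVs disagree in shape: {shapes}")
    return SignalEpochs(
        data=np.stack(trials), fs=fs, labels=np.asarray(labels, dtype=int)
    )


def save_features(batch: FeatureBatch, path: str | Path) -> None:
    path = Path(path)
    trial_index = (
        batch.trial_index
        if batch.trial_index is not None
        else np.full(batch.n_samples, -1)
    )
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=batch.x)
            f.create_dataset("y", data=batch.y)
            f.create_dataset("trial_index", data=trial_index)
            f.attrs["band_selector"] = batch.band_selector
    else:
        np.savez(
            path,
            x=batch.x,
            y=batch.y,
            trial_index=trial_index,
            band_selector=np.array(batch.band_selector),
        )


def load_features(path: str | Path) -> FeatureBatch:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            ti = f["trial_index"][()]
            return FeatureBatch(
                x=f["x"][()],
                y=f["y"][()],
                band_selector=str(f.attrs["band_selector"]),
                trial_index=None if np.all(ti < 0) else ti,
            )
    with np.load(path) as z:
        ti = z["trial_index"]
        return FeatureBatch(
            x=z["x"],
            y=z["y"],
            band_selector=str(z["band_selector"]),
            trial_index=None if np.all(ti < 0) else ti,
        )


def save_matrix_csv(
    weights: np.ndarray,
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write an N x N matrix as CSV (header = channel names) with an
    optional JSON sidecar of estimation/fusion metadata."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    names = list(channel_names) if channel_names is not None else [
        f"ch{i:02d}" for i in range(n)
    ]
    pd.DataFrame(weights, columns=names).to_csv(path, index=False)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )


def load_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def save_graph(graph: ConnectivityMatrix | FusedGraph, path: str | Path) -> None:
    if isinstance(graph, ConnectivityMatrix):
        sidecar = {
            "kind": graph.kind,
            "directed": graph.directed,
            "params": {
                k: v for k, v in graph.params.items() if _json_safe(v)
            },
        }
    else:
        sidecar = {
            "strategy": graph.strategy,
            "components": list(graph.components),
            "threshold_spec": graph.threshold_spec,
        }
    save_matrix_csv(graph.weights, path, graph.channel_names, sidecar)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def save_model(model: ChebGCNClassifier, path: str | Path) -> None:
    """Checkpoint a fitted classifier: one NPZ archive holding the learned
    arrays, the fused adjacency, and a JSON config manifest."""
    manifest = {
        k: v
        for k, v in model.get_params().items()
        if k not in ("adjacency", "grid_index")
    }
    arrays = {
        "manifest": np.array(json.dumps(manifest, sort_keys=True)),
        "classes": model.classes_,
        "h_fuse": model.operator_.h_fuse,
        "feature_mean": model.feature_mean_,
        "feature_scale": model.feature_scale_,
        "loss_curve": np.array(model.loss_curve_),
    }
    if model.grid_index is not None:
        arrays["grid_index"] = np.asarray(model.grid_index, dtype=int)
    for k, v in model.params_.items():
        arrays[f"param_{k}"] = v
    np.savez(path, **arrays)


def load_model(path: str | Path) -> ChebGCNClassifier:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        model = ChebGCNClassifier(**manifest)
        model.adjacency = z["h_fuse"]
        if "grid_index" in z:
            model.grid_index = z["grid_index"]
        model.classes_ = z["classes"]
        model.operator_ = build_spectral_operator(z["h_fuse"])
        from .gcn import cheb_polynomials

        model.cheb_terms_ = np.stack(
            cheb_polynomials(model.operator_, model.cheb_order)
        )
        model.feature_mean_ = z["feature_mean"]
        model.feature_scale_ = z["feature_scale"]
        model.loss_curve_ = list(z["loss_curve"])
        model.params_ = {
            k[len("param_") :]: z[k] for k in z.files if k.startswith("param_")
        }
        model.n_features_in_ = int(np.prod(model.feature_mean_.shape))
    return model


def save_training_log(loss_curve: Sequence[float], path: str | Path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(len(loss_curve)), "loss": loss_curve}
    ).to_csv(path, index=False)
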