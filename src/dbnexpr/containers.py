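"""Versioned model containers (.npz) with bit-exact round-trip.

Each container stores a format version, a kind tag, the numeric arrays
as float64 and a JSON metadata blob (architecture string, encoding, code
layer).  Fitted scaling parameters travel with the model so test data are
always scaled exactly as the training data were.
"""

from __future__ import annotations

import json

import numpy as np

from .autoencoder import AutoencoderModel
from .network import NetworkModel, OutputEncoding
from .rbm import MinMaxScaler, RBMModel

__all__ = [
    "save_network",
    "load_network",
    "save_stack",
    "load_stack",
    "save_autoencoder",
    "load_autoencoder",
]

_FORMAT_VERSION = 1


def _scaler_arrays(scaler: MinMaxScaler | None) -> dict[str, np.ndarray]:
    if scaler is None or scaler.minimum is None:
        return {}
    return {"scale_min": scaler.minimum, "scale_range": scaler.value_range}


def _load_scaler(z) -> MinMaxScaler | None:
    if "scale_min" not in z:
        return None
    return MinMaxScaler(minimum=z["scale_min"], value_range=z["scale_range"])


def save_network(
    m: NetworkModel,
    path,
    encoding: OutputEncoding | None = None,
    scaler: MinMaxScaler | None = None,
    architecture: str | None = None,
) -> None:
    meta = {
        "kind": "network",
        "layer_sizes": m.layer_sizes,
        "architecture": architecture,
        "encoding": None if encoding is None else
        {"mode": encoding.mode, "p": encoding.p},
    }
    arrays = {f"w{l}": w for l, w in enumerate(m.weights)}
    arrays |= {f"b{l}": b for l, b in enumerate(m.biases)}
    np.savez(path, format_version=np.int64(_FORMAT_VERSION),
             meta=np.array(json.dumps(meta)), **arrays, **_scaler_arrays(scaler))


def load_network(path) -> tuple[NetworkModel, OutputEncoding | None,
                                MinMaxScaler | None]:
    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported container version")
        meta = json.loads(str(z["meta"]))
        if meta["kind"] not in ("network", "autoencoder"):
            raise ValueError(f"container holds a {meta['kind']}, not a network")
        sizes = meta["layer_sizes"]
        n = len(sizes) - 1
        net = NetworkModel(sizes, [z[f"w{l}"] for l in range(n)],
                           [z[f"b{l}"] for l in range(n)])
        enc = (OutputEncoding(**meta["encoding"])
               if meta.get("encoding") else None)
        return net, enc, _load_scaler(z)


def save_stack(stack: list[RBMModel], path,
               scaler: MinMaxScaler | None = None) -> None:
    meta = {"kind": "rbm-stack", "n_rbms": len(stack)}
    arrays: dict[str, np.ndarray] = {}
    for i, r in enumerate(stack):
        arrays[f"rbm{i}_w"] = r.weights
        arrays[f"rbm{i}_vb"] = r.visible_bias
        arrays[f"rbm{i}_hb"] = r.hidden_bias
    np.savez(path, format_version=np.int64(_FORMAT_VERSION),
             meta=np.array(json.dumps(meta)), **arrays, **_scaler_arrays(scaler))


def load_stack(path) -> tuple[list[RBMModel], MinMaxScaler | None]:
    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported container version")
        meta = json.loads(str(z["meta"]))
        if meta["kind"] != "rbm-stack":
            raise ValueError(f"container holds a {meta['kind']}, not an RBM stack")
        stack = [
            RBMModel(z[f"rbm{i}_w"], z[f"rbm{i}_vb"], z[f"rbm{i}_hb"])
            for i in range(meta["n_rbms"])
        ]
        return stack, _load_scaler(z)


def save_autoencoder(m: AutoencoderModel, path,
                     scaler: MinMaxScaler | None = None) -> None:
    meta = {
        "kind": "autoencoder",
        "layer_sizes": m.network.layer_sizes,
        "architecture": None,
        "encoding": None,
        "code_layer_index": m.code_layer_index,
    }
    arrays = {f"w{l}": w for l, w in enumerate(m.network.weights)}
    arrays |= {f"b{l}": b for l, b in enumerate(m.network.biases)}
    np.savez(path, format_version=np.int64(_FORMAT_VERSION),
             meta=np.array(json.dumps(meta)), **arrays, **_scaler_arrays(scaler))


def load_autoencoder(path) -> tuple[AutoencoderModel, MinMaxScaler | None]:
    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported container version")
        meta = json.loads(str(z["meta"]))
        if meta["kind"] != "autoencoder":
            raise ValueError(f"container holds a {meta['kind']}, not an autoencoder")
        sizes = meta["layer_sizes"]
        n = len(sizes) - 1
        net = NetworkModel(sizes, [z[f"w{l}"] for l in range(n)],
                           [z[f"b{l}"] for l in range(n)])
        return (AutoencoderModel(net, meta["code_layer_index"]),
                _load_scaler(z))
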